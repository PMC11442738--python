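"""Derived analysis variables: NDVI, water-use efficiency, canopy-partitioned
transpiration, and unit conversion to a canonical water unit.

The canonical internal water unit is liters per hectare per day, so that
seasonal totals read directly as liters per hectare. 1 mm of water depth over
1 ha is 10,000 L; latent-heat flux in W m^-2 converts to depth via the latent
heat of vaporization (default 2.45 MJ kg^-1) and 86,400 s per day.

Transpiration is estimated by canopy partitioning: multiplying a day's ET by
that day's canopy fraction attributes the canopy-covered share of the water
flux to plants, with the remainder treated as soil evaporation. The same
scaling applied to WUE gives a transpiration-only WUE. Because real canopy
products are sparser than ET products, a day's canopy fraction may be borrowed
from the nearest canopy observation within a configurable window (default
+/- 8 days); days with no canopy observation in the window are dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "MM_TO_L_PER_HA",
    "compute_ndvi",
    "derive_wue",
    "partition_canopy",
    "to_liters_per_ha",
    "ndvi_to_canopy",
    "assemble_flux_series",
]

log = logging.getLogger(__name__)

#: 1 mm of water over 1 hectare, in liters
MM_TO_L_PER_HA = 10_000.0

#: default latent heat of vaporization, MJ per kg of water
LATENT_HEAT_MJ_PER_KG = 2.45

#: columns of the per-field daily flux table
FLUX_COLUMNS = [
    "field_id",
    "crop",
    "date",
    "et",
    "canopy_fraction",
    "gpp",
    "wue",
    "ndvi",
    "transpiration",
    "wue_t",
]


def compute_ndvi(red, nir):
    """Normalized difference vegetation index, (NIR - Red)/(NIR + Red).

    Reflectances must be nonnegative; where red + nir == 0 the index is
    undefined and NaN is returned (with a log entry). Always in [-1, 1].
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if np.any(red < 0) or np.any(nir < 0):
        raise ValueError("reflectances must be nonnegative")
    total = red + nir
    bad = total == 0
    n_bad = int(np.count_nonzero(bad & np.isfinite(total)))
    if n_bad:
        log.info("compute_ndvi: %d records with zero total reflectance dropped", n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bad, np.nan, (nir - red) / np.where(bad, 1.0, total))
    return out if out.ndim else float(out)


def derive_wue(gpp_sources, et_mass):
    """WUE in g C per kg H2O from one or more GPP sources and ET mass flux.

    ``gpp_sources`` is a sequence of arrays/scalars in g C m^-2 d^-1 (e.g.
    two satellite GPP products, averaged); ``et_mass`` is in kg H2O m^-2 d^-1
    (numerically equal to mm/d). Where ET is zero or missing the quotient is
    undefined and NaN is returned with a log entry.
    """
    if isinstance(gpp_sources, (list, tuple)):
        sources = [np.asarray(g, dtype=float) for g in gpp_sources if g is not None]
    else:
        sources = [np.asarray(gpp_sources, dtype=float)]
    if not sources:
        raise ValueError("at least one GPP source is required")
    gpp = np.nanmean(np.broadcast_arrays(*sources), axis=0) if len(sources) > 1 else sources[0]
    et = np.asarray(et_mass, dtype=float)
    bad = ~(et > 0)
    n_bad = int(np.count_nonzero(bad & np.isfinite(et)))
    if n_bad:
        log.info("derive_wue: %d records with nonpositive ET dropped", n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bad, np.nan, gpp / np.where(bad, 1.0, et))
    return out if out.ndim else float(out)


def to_liters_per_ha(value, unit: str, latent_heat_mj_per_kg: float = LATENT_HEAT_MJ_PER_KG):
    """Convert a water flux to the canonical L ha^-1 d^-1.

    Supported units: ``mm_per_day`` (x 10,000), ``W_per_m2`` (latent-heat
    flux; 86,400 s/d over lambda = 2.45 MJ/kg gives 0.0352653 mm/d per W/m^2,
    then x 10,000), and ``L_per_ha_day`` (identity).
    """
    value = np.asarray(value, dtype=float)
    if np.any(value[np.isfinite(value)] < 0):
        raise ValueError("water fluxes must be nonnegative")
    if unit == "mm_per_day":
        out = value * MM_TO_L_PER_HA
    elif unit == "W_per_m2":
        mm = value * 86_400.0 / (latent_heat_mj_per_kg * 1e6)
        out = mm * MM_TO_L_PER_HA
    elif unit == "L_per_ha_day":
        out = value
    else:
        raise ValueError(f"unknown water unit {unit!r}")
    return out if out.ndim else float(out)


def ndvi_to_canopy(ndvi, mode: str = "direct", ndvi_min: float = 0.0, ndvi_max: float = 1.0):
    """Map NDVI to a canopy fraction in [0, 1].

    ``direct`` clips NDVI to [0, 1]; ``rescale`` applies a linear stretch
    (ndvi - ndvi_min)/(ndvi_max - ndvi_min) before clipping. Both are offered
    because greenness-to-cover mappings are calibration choices.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    if mode == "direct":
        out = np.clip(ndvi, 0.0, 1.0)
    elif mode == "rescale":
        if ndvi_max <= ndvi_min:
            raise ValueError("ndvi_max must exceed ndvi_min")
        out = np.clip((ndvi - ndvi_min) / (ndvi_max - ndvi_min), 0.0, 1.0)
    else:
        raise ValueError(f"unknown ndvi_to_canopy mode {mode!r}")
    return out if out.ndim else float(out)


def partition_canopy(flux: pd.DataFrame) -> pd.DataFrame:
    """Add canopy-partitioned transpiration and transpiration-only WUE.

    ``transpiration = et * canopy_fraction`` and ``wue_t = wue *
    canopy_fraction``. Records whose canopy fraction lies outside [0, 1] are
    rejected (dropped with a log entry); rows lacking a canopy fraction keep
    NaN derived values.
    """
    fc = flux["canopy_fraction"]
    bad = fc.notna() & ((fc < 0) | (fc > 1))
    if bad.any():
        log.warning("partition_canopy: rejected %d records with canopy outside [0,1]", int(bad.sum()))
        flux = flux.loc[~bad]
    out = flux.copy()
    out["transpiration"] = out["et"] * out["canopy_fraction"]
    if "wue" in out:
        out["wue_t"] = out["wue"] * out["canopy_fraction"]
    return out


def assemble_flux_series(
    stats: pd.DataFrame,
    et_unit: str = "mm_per_day",
    canopy_pairing_window_days: int = 8,
    canopy_source: str = "canopy",
    ndvi_to_canopy_mode: str = "direct",
    ndvi_min: float = 0.0,
    ndvi_max: float = 1.0,
    latent_heat_mj_per_kg: float = LATENT_HEAT_MJ_PER_KG,
) -> pd.DataFrame:
    """Build the per-field daily flux table from long-form zonal statistics.

    Parameters
    ----------
    stats:
        Long table with columns field_id, crop, date, variable, mean
        (:func:`cropwater.ingest.zonal_daily_stats` output, ideally after
        :func:`cropwater.ingest.drop_empty`). Recognized variables: ``et``,
        ``canopy``, ``wue``, ``gpp`` (or several ``gpp*`` sources), ``red``,
        ``nir``.
    et_unit:
        Unit of the incoming ET means; converted to L ha^-1 d^-1 here, once.
    canopy_pairing_window_days:
        How far (in days) a canopy observation may be borrowed to pair with
        an ET date; 0 requires same-day canopy.
    canopy_source:
        ``"canopy"`` uses the canopy-percentage product; ``"ndvi"`` derives
        canopy fraction from NDVI (for eras before a canopy product exists).

    Returns
    -------
    Wide per-field daily table with columns et, canopy_fraction, gpp, wue,
    ndvi, transpiration, wue_t; water unit L ha^-1 d^-1 throughout.
    """
    if stats.empty:
        return pd.DataFrame(columns=FLUX_COLUMNS)
    try:
        wide = stats.pivot(
            index=["field_id", "crop", "date"], columns="variable", values="mean"
        ).reset_index()
    except ValueError:  # duplicate field/date/variable entries: average them
        wide = stats.pivot_table(
            index=["field_id", "crop", "date"], columns="variable", values="mean", aggfunc="mean"
        ).reset_index()
    wide.columns.name = None
    wide["date"] = pd.to_datetime(wide["date"])

    if {"red", "nir"}.issubset(wide.columns):
        wide["ndvi"] = compute_ndvi(wide["red"], wide["nir"])
    elif "ndvi" not in wide:
        wide["ndvi"] = np.nan

    if "et" not in wide:
        raise ValueError("flux assembly requires an 'et' variable")
    et_mm = to_liters_per_ha(wide["et"].to_numpy(), et_unit, latent_heat_mj_per_kg) / MM_TO_L_PER_HA
    wide["et_mm"] = et_mm
    wide["et"] = et_mm * MM_TO_L_PER_HA

    # canopy fraction: from the canopy product (percent or fraction), or NDVI
    if canopy_source == "ndvi":
        wide["canopy_fraction"] = ndvi_to_canopy(
            wide["ndvi"], ndvi_to_canopy_mode, ndvi_min, ndvi_max
        )
    else:
        if "canopy" in wide:
            fc = wide["canopy"].astype(float)
            # a canopy *percentage* product is rescaled to a fraction
            if np.nanmax(fc.to_numpy(), initial=0.0) > 1.5:
                fc = fc / 100.0
            wide["canopy_fraction"] = fc
        else:
            wide["canopy_fraction"] = np.nan
        wide = _pair_canopy(wide, canopy_pairing_window_days)

    # WUE: prefer the product's own WUE, else mean of GPP sources over ET mass
    gpp_cols = [c for c in wide.columns if c == "gpp" or c.startswith("gpp_")]
    if gpp_cols:
        wide["gpp"] = wide[gpp_cols].mean(axis=1)
    else:
        wide["gpp"] = np.nan
    quotient = derive_wue(wide["gpp"].to_numpy(), wide["et_mm"].to_numpy())
    if "wue" in wide:
        wide["wue"] = wide["wue"].astype(float).fillna(pd.Series(quotient, index=wide.index))
    else:
        wide["wue"] = quotient

    out = partition_canopy(wide)
    return out[FLUX_COLUMNS].sort_values(["crop", "field_id", "date"], ignore_index=True)


def _pair_canopy(wide: pd.DataFrame, window_days: int) -> pd.DataFrame:
    """Fill missing same-day canopy fractions from the nearest observation
    within +/- window_days, per field; unmatched days are dropped later by
    the seasonal aggregation (their derived values stay NaN)."""
    have = wide["canopy_fraction"].notna()
    if window_days <= 0 or have.all() or not have.any():
        return wide
    tol = pd.Timedelta(days=window_days)
    pieces = []
    for _, grp in wide.groupby("field_id", sort=False):
        grp = grp.sort_values("date")
        obs = grp.loc[grp["canopy_fraction"].notna(), ["date", "canopy_fraction"]]
        if obs.empty:
            pieces.append(grp)
            continue
        paired = pd.merge_asof(
            grp.drop(columns="canopy_fraction").sort_values("date"),
            obs.rename(columns={"canopy_fraction": "fc_near"}),
            on="date",
            direction="nearest",
            tolerance=tol,
        )
        paired["canopy_fraction"] = paired.pop("fc_near")
        pieces.append(paired)
    return pd.concat(pieces, ignore_index=True)
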