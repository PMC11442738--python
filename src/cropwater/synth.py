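"""Synthetic satellite-like scenes with known ground-truth crop water fluxes.

Real comparisons of crop water use rest on daily thermal/optical satellite
products (ECOSTRESS-style 70 m ET, water-use efficiency and canopy-percentage
layers; Landsat/MODIS-style ET, GPP and surface-reflectance layers) clipped to
labeled agricultural fields. Those archives cannot ship with a package, so this
module generates scenes whose per-crop daily flux curves are known exactly:
every downstream stage — zonal extraction, flux derivation, seasonal
aggregation, ratio estimation — can then be tested against analytic truth.

A scene is a shared pixel grid, a set of rectangular field polygons each
labeled with a crop, a categorical crop-class raster consistent with those
polygons, a stack of daily rasters per variable, and a site air-temperature
series. Pixel values are the crop's deterministic curve value for that day
plus independent Gaussian noise (ET only), truncated at zero; whole
(crop, variable, day) slabs go missing at a configurable rate to mimic
satellite revisit gaps. Everything is reproducible from a single seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .grid import RasterGrid

__all__ = [
    "CropProfile",
    "FieldSpec",
    "SyntheticScene",
    "generate_site_season",
    "true_season_total",
    "true_season_ratio",
    "default_profiles",
]

#: variables a scene can carry; red/nir are reflectances, the rest fluxes
SCENE_VARIABLES = ("et", "canopy", "wue", "gpp", "red", "nir")

#: total red+nir reflectance used to encode canopy fraction as NDVI exactly
_REFLECTANCE_TOTAL = 0.6


@dataclass(frozen=True)
class CropProfile:
    """Ground-truth seasonal flux curves for one crop.

    The daily ET curve is a baseline plus a Gaussian bump:
    ``et(d) = et_base + et_peak_amplitude * exp(-0.5 ((d - peak)/width)^2)``
    in mm per day. Canopy fraction follows a logistic rise and fall,
    ``canopy_max * sigmoid((d - rise)/rise_rate) * sigmoid((fall - d)/fall_rate)``,
    always inside [0, 1]. Water-use efficiency is a constant ``wue_base`` in
    g C per kg H2O, and the synthetic GPP layer is generated as
    ``wue_base * ET`` (1 mm of water over 1 m^2 is 1 kg), so that GPP/ET
    recovers ``wue_base`` exactly.

    ``pixel_noise_sd`` (mm/d) is the per-pixel, per-day Gaussian noise on ET;
    ``missing_day_rate`` is the probability that a given (variable, day) slab
    of this crop's pixels is absent from the scene.
    """

    name: str
    season_start: dt.date
    season_end: dt.date
    et_base: float = 2.5
    et_peak_amplitude: float = 3.0
    et_peak_day: dt.date | None = None
    et_width_days: float = 45.0
    canopy_max: float = 0.9
    canopy_rise_day: dt.date | None = None
    canopy_rise_rate: float = 10.0
    canopy_fall_day: dt.date | None = None
    canopy_fall_rate: float = 8.0
    wue_base: float = 2.0
    pixel_noise_sd: float = 1.0
    missing_day_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.season_start >= self.season_end:
            raise ValueError(f"{self.name}: season_start must precede season_end")
        if self.et_base < 0 or self.et_peak_amplitude < 0:
            raise ValueError(f"{self.name}: ET curve parameters must be nonnegative")
        if not 0.0 <= self.canopy_max <= 1.0:
            raise ValueError(f"{self.name}: canopy_max must lie in [0, 1]")
        if not 0.0 <= self.missing_day_rate <= 1.0:
            raise ValueError(f"{self.name}: missing_day_rate must lie in [0, 1]")
        if self.pixel_noise_sd < 0:
            raise ValueError(f"{self.name}: pixel_noise_sd must be nonnegative")
        # default phenology anchors derived from the season window
        mid = self.season_start + (self.season_end - self.season_start) / 2
        if self.et_peak_day is None:
            object.__setattr__(self, "et_peak_day", mid)
        if self.canopy_rise_day is None:
            object.__setattr__(
                self, "canopy_rise_day", self.season_start + dt.timedelta(days=30)
            )
        if self.canopy_fall_day is None:
            object.__setattr__(
                self, "canopy_fall_day", self.season_end - dt.timedelta(days=20)
            )

    def _ordinals(self, dates) -> np.ndarray:
        return np.asarray([d.toordinal() for d in dates], dtype=float)

    def et_curve(self, dates) -> np.ndarray:
        """Noise-free daily ET in mm/d for the given dates."""
        d = self._ordinals(dates)
        z = (d - self.et_peak_day.toordinal()) / self.et_width_days
        return self.et_base + self.et_peak_amplitude * np.exp(-0.5 * z**2)

    def canopy_curve(self, dates) -> np.ndarray:
        """Noise-free canopy fraction in [0, 1] for the given dates."""
        d = self._ordinals(dates)
        rise = 1.0 / (1.0 + np.exp(-(d - self.canopy_rise_day.toordinal()) / self.canopy_rise_rate))
        fall = 1.0 / (1.0 + np.exp((d - self.canopy_fall_day.toordinal()) / self.canopy_fall_rate))
        return np.clip(self.canopy_max * rise * fall, 0.0, 1.0)

    def scaled(self, et_factor: float) -> "CropProfile":
        """Copy of this profile with the whole ET curve multiplied by a factor."""
        return replace(
            self,
            et_base=self.et_base * et_factor,
            et_peak_amplitude=self.et_peak_amplitude * et_factor,
        )


@dataclass(frozen=True)
class FieldSpec:
    """Field layout: rectangular fields of field_rows x field_cols pixels tiled
    over the grid with a one-pixel gap, assigned to crops round-robin."""

    field_rows: int = 5
    field_cols: int = 5
    gap: int = 1


@dataclass
class SyntheticScene:
    """A generated site-season: grid, fields, class map, daily rasters, truth.

    ``daily_layers`` maps date -> {variable -> 2-D float array}; pixels outside
    any field are NaN (nodata), as are pixels of a crop whose slab is missing
    that day. ``class_map`` holds an integer crop index per pixel (-1 for
    background) with ``class_labels`` giving the crop name per index.
    """

    grid: RasterGrid
    field_table: pd.DataFrame  # field_id, crop, polygon (shapely), row0, col0, rows, cols
    class_map: np.ndarray
    class_labels: list[str]
    daily_layers: dict[dt.date, dict[str, np.ndarray]]
    temperature: pd.Series
    truth: dict = field(default_factory=dict)

    @property
    def dates(self) -> list[dt.date]:
        return sorted(self.daily_layers)

    def field_polygons(self) -> list[tuple[str, str, Polygon]]:
        """(field_id, crop, polygon) triples for zonal extraction."""
        return list(
            self.field_table[["field_id", "crop", "polygon"]].itertuples(index=False, name=None)
        )


def _layout_fields(
    grid: RasterGrid, profiles: list[CropProfile], spec: FieldSpec
) -> tuple[pd.DataFrame, np.ndarray]:
    """Tile rectangular fields over the grid and rasterize the class map."""
    step_r = spec.field_rows + spec.gap
    step_c = spec.field_cols + spec.gap
    n_block_rows = (grid.rows + spec.gap) // step_r
    n_block_cols = (grid.cols + spec.gap) // step_c
    if n_block_rows * n_block_cols < len(profiles):
        raise ValueError(
            f"grid {grid.rows}x{grid.cols} too small for one "
            f"{spec.field_rows}x{spec.field_cols} field per crop"
        )
    class_map = np.full(grid.shape, -1, dtype=np.int32)
    s = grid.pixel_size_m
    rows = []
    k = 0
    for br in range(n_block_rows):
        for bc in range(n_block_cols):
            crop = profiles[k % len(profiles)].name
            r0, c0 = br * step_r, bc * step_c
            r1, c1 = r0 + spec.field_rows, c0 + spec.field_cols
            class_map[r0:r1, c0:c1] = k % len(profiles)
            poly = Polygon(
                [(c0 * s, r0 * s), (c1 * s, r0 * s), (c1 * s, r1 * s), (c0 * s, r1 * s)]
            )
            rows.append(
                {
                    "field_id": f"{crop}_{k:03d}",
                    "crop": crop,
                    "polygon": poly,
                    "row0": r0,
                    "col0": c0,
                    "rows": spec.field_rows,
                    "cols": spec.field_cols,
                }
            )
            k += 1
    return pd.DataFrame(rows), class_map


def generate_site_season(
    profiles,
    grid: RasterGrid,
    date_range,
    seed: int,
    field_spec: FieldSpec = FieldSpec(),
    variables=SCENE_VARIABLES,
) -> SyntheticScene:
    """Generate one synthetic site-season.

    Parameters
    ----------
    profiles:
        One :class:`CropProfile` per crop present at the site. The date range
        must cover every profile's growing season.
    grid:
        The shared pixel grid.
    date_range:
        Iterable of :class:`datetime.date` (or a pandas DatetimeIndex); the
        days for which layers are generated.
    seed:
        Seed for all randomness (noise, missing days, temperature jitter).
        The same seed reproduces the scene bit for bit.
    variables:
        Subset of ``("et", "canopy", "wue", "gpp", "red", "nir")`` to
        generate; trimming unused layers keeps large simulation studies fast.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one CropProfile is required")
    dates = [d.date() if hasattr(d, "date") else d for d in date_range]
    if len(set(dates)) != len(dates):
        raise ValueError("date_range contains duplicates")
    dates = sorted(dates)
    for p in profiles:
        if p.season_start < dates[0] or p.season_end > dates[-1]:
            raise ValueError(f"date_range does not cover the season of {p.name!r}")
    unknown = set(variables) - set(SCENE_VARIABLES)
    if unknown:
        raise ValueError(f"unknown scene variables: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    field_table, class_map = _layout_fields(grid, profiles, field_spec)
    labels = [p.name for p in profiles]
    n_days = len(dates)

    # per-crop curve values for every day, and per-crop missing-day masks
    layers = {d: {} for d in dates}
    for var in variables:
        # allocate one (n_days, rows, cols) stack per variable
        stack = np.full((n_days, grid.rows, grid.cols), np.nan, dtype=np.float64)
        for ci, prof in enumerate(profiles):
            pix = class_map == ci
            missing = rng.random(n_days) < prof.missing_day_rate
            if var == "et":
                vals = prof.et_curve(dates)[:, None]
                noise = rng.normal(0.0, prof.pixel_noise_sd or 1.0, (n_days, int(pix.sum())))
                if prof.pixel_noise_sd == 0:
                    noise[:] = 0.0
                crop_vals = np.maximum(vals + noise, 0.0)
            elif var == "canopy":
                crop_vals = np.broadcast_to(
                    prof.canopy_curve(dates)[:, None], (n_days, int(pix.sum()))
                )
            elif var == "wue":
                crop_vals = np.full((n_days, int(pix.sum())), prof.wue_base)
            elif var == "gpp":
                # g C m-2 d-1 = wue (g C / kg) * ET (mm == kg m-2); reuse the
                # noisy ET field when present so GPP/ET returns wue exactly
                if "et" in layers[dates[0]] or "et" in variables:
                    pass  # filled in a second pass below
                crop_vals = None
            elif var in ("red", "nir"):
                fc = prof.canopy_curve(dates)[:, None]
                half = _REFLECTANCE_TOTAL / 2.0
                crop_vals = half * (1.0 - fc) if var == "red" else half * (1.0 + fc)
                crop_vals = np.broadcast_to(crop_vals, (n_days, int(pix.sum())))
            if var == "gpp":
                continue
            crop_vals = np.array(crop_vals, copy=True)
            crop_vals[missing, :] = np.nan
            stack[:, pix] = crop_vals
        for di, d in enumerate(dates):
            if np.all(np.isnan(stack[di])):
                continue  # whole day absent for this variable
            layers[d][var] = stack[di]

    if "gpp" in variables:
        # second pass so GPP can reuse the realized (noisy) ET field
        for ci, prof in enumerate(profiles):
            pix = class_map == ci
            missing = rng.random(n_days) < prof.missing_day_rate
            clean_et = prof.et_curve(dates)
            for di, d in enumerate(dates):
                if missing[di]:
                    continue
                et_layer = layers[d].get("et")
                et_vals = et_layer[pix] if et_layer is not None else np.full(int(pix.sum()), clean_et[di])
                gpp = layers[d].setdefault(
                    "gpp", np.full(grid.shape, np.nan, dtype=np.float64)
                )
                gpp[pix] = prof.wue_base * et_vals

    layers = {d: v for d, v in layers.items() if v}

    # smooth seasonal air-temperature cycle with day-to-day weather jitter
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    temps = 15.0 + 10.0 * np.sin(2 * np.pi * (doy - 110.0) / 365.25) + rng.normal(0, 1.5, n_days)
    temperature = pd.Series(temps, index=pd.DatetimeIndex(dates), name="tair_c")

    return SyntheticScene(
        grid=grid,
        field_table=field_table,
        class_map=class_map,
        class_labels=labels,
        daily_layers=layers,
        temperature=temperature,
        truth={"profiles": profiles, "seed": seed, "field_spec": field_spec},
    )


def true_season_total(profile: CropProfile, window) -> float:
    """Noise-free seasonal ET total (mm) of a profile over a date window,
    by day-by-day summation of the curve."""
    start, end = window
    dates = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
    return float(profile.et_curve(dates).sum())


def true_season_ratio(profile_a: CropProfile, profile_b: CropProfile, window) -> float:
    """Ground-truth seasonal ET ratio total(a)/total(b) over a window.

    This is the quantity the full pipeline should recover from noisy scenes;
    it is computed directly from the noise-free curves.
    """
    denom = true_season_total(profile_b, window)
    if denom == 0.0:
        raise ZeroDivisionError(f"profile {profile_b.name!r} has zero consumption in window")
    return true_season_total(profile_a, window) / denom


def default_profiles(year: int = 2022) -> list[CropProfile]:
    """Profiles emulating the study's crop set over a late-May to early-November
    Northern-Hemisphere season: a low-water chia crop against alfalfa, corn and
    soybean with progressively heavier ET curves and lower WUE."""
    start = dt.date(year, 5, 25)
    end = dt.date(year, 11, 5)
    common = dict(season_start=start, season_end=end)
    return [
        CropProfile(name="chia", et_base=2.0, et_peak_amplitude=2.6, wue_base=2.3, **common),
        CropProfile(name="alfalfa", et_base=2.6, et_peak_amplitude=3.2, wue_base=2.0, **common),
        CropProfile(name="corn", et_base=2.3, et_peak_amplitude=3.1, wue_base=2.0, **common),
        CropProfile(name="soybean", et_base=2.3, et_peak_amplitude=3.0, wue_base=1.9, **common),
    ]
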