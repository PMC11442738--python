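"""Cross-season crop-versus-chia ratio estimation and temperature response.

The central statistic is a per-season ratio of seasonal water-use quantities:
for consumption variables (seasonal ET/transpiration totals and daily means)
the ratio is crop/chia, so values above 1 mean the reference crop (chia) used
less water; for efficiency variables (WUE, transpiration-only WUE) it is
chia/crop, so values above 1 mean chia fixed more carbon per unit water.
Per-season ratios are averaged across site-seasons; uncertainty is the
standard error of that mean (sample standard deviation across seasons over
sqrt(n)). Ratios are also rendered as percent differences: for a crop/chia
ratio R the "percent less water used by chia" is (1 - 1/R) x 100; for a
chia/crop ratio, "percent more" is (R - 1) x 100. Both the raw ratio and the
percent are always reported, since the percent convention is a rendering
choice.

Daily ratio series (same-date crop and chia values) support a temperature
response analysis: each daily ratio is paired with its site's air temperature
and an ordinary least-squares line is fitted, with a two-tailed t-test on the
slope (t = slope / SE(slope), n - 2 degrees of freedom).

The module exposes both the individual operations and a model-style facade,
:class:`WaterUseComparison`, whose ``fit()`` returns a
:class:`WaterUseComparisonResults` carrying the ratio table, standard errors,
regressions, a ``summary()`` text report and a bar-chart plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "season_ratio",
    "summarize_ratios",
    "percent_difference",
    "daily_ratio_series",
    "temp_regression",
    "RatioSummary",
    "TempRegression",
    "WaterUseComparison",
    "WaterUseComparisonResults",
]

log = logging.getLogger(__name__)

#: comparison parameters and their default ratio orientation
PARAMETER_ORIENTATION = {
    "ET_total": "crop_over_chia",
    "T_total": "crop_over_chia",
    "ET_daily": "crop_over_chia",
    "T_daily": "crop_over_chia",
    "WUE": "chia_over_crop",
    "WUE_T": "chia_over_crop",
}

_PARAM_COLUMN = {
    "ET_total": "et_total",
    "T_total": "t_total",
    "ET_daily": "et_daily_mean",
    "T_daily": "t_daily_mean",
    "WUE": "wue_mean",
    "WUE_T": "wue_t_mean",
}


def season_ratio(crop_value: float, chia_value: float, orientation: str = "crop_over_chia") -> float:
    """One season's ratio between a crop's value and chia's."""
    if not (crop_value > 0 and chia_value > 0):
        raise ValueError("season values must be positive for a ratio")
    if orientation == "crop_over_chia":
        return crop_value / chia_value
    if orientation == "chia_over_crop":
        return chia_value / crop_value
    raise ValueError(f"unknown orientation {orientation!r}")


def percent_difference(mean_ratio: float, orientation: str) -> float:
    """Render a mean ratio as a percent difference.

    crop_over_chia: percent less water used by chia, (1 - 1/R) x 100.
    chia_over_crop: percent more carbon per unit water, (R - 1) x 100.
    """
    if orientation == "crop_over_chia":
        return (1.0 - 1.0 / mean_ratio) * 100.0
    if orientation == "chia_over_crop":
        return (mean_ratio - 1.0) * 100.0
    raise ValueError(f"unknown orientation {orientation!r}")


@dataclass(frozen=True)
class RatioSummary:
    """Cross-season mean ratio with its standard error."""

    mean: float
    se: float  # NaN when only one season
    n_seasons: int
    orientation: str
    percent: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        se = f"{self.se:.3f}" if np.isfinite(self.se) else "n/a"
        return f"R={self.mean:.4f} (SE={se}, n={self.n_seasons}), {self.percent:+.1f}%"


def summarize_ratios(ratios, orientation: str = "crop_over_chia") -> RatioSummary:
    """Mean and standard error of per-season ratios.

    ``ratios`` is a sequence (or mapping site_season -> value) of per-season
    ratios, one per site-season. SE is the n-1 sample standard deviation over
    sqrt(n); with a single season it is NaN and flagged in the log.
    """
    vals = np.asarray(list(ratios.values()) if isinstance(ratios, dict) else list(ratios), float)
    if vals.size == 0:
        raise ValueError("at least one season ratio is required")
    if np.any(vals <= 0):
        raise ValueError("season ratios must be positive")
    mean = float(vals.mean())
    if vals.size >= 2:
        se = float(vals.std(ddof=1) / np.sqrt(vals.size))
    else:
        se = float("nan")
        log.info("summarize_ratios: single season, SE undefined")
    return RatioSummary(mean, se, int(vals.size), orientation, percent_difference(mean, orientation))


def daily_ratio_series(
    crop_daily: pd.Series, chia_daily: pd.Series, orientation: str = "crop_over_chia"
) -> tuple[pd.Series, float]:
    """Per-date ratios over the exact date intersection, plus their mean.

    Dates present in only one series are dropped (and logged). Raises when
    the two series share no dates.
    """
    joined = pd.concat([crop_daily.rename("crop"), chia_daily.rename("chia")], axis=1, join="inner")
    joined = joined.dropna()
    n_dropped = max(len(crop_daily), len(chia_daily)) - len(joined)
    if joined.empty:
        raise ValueError("crop and chia daily series share no dates")
    if n_dropped:
        log.info("daily_ratio_series: %d unmatched/invalid dates dropped", n_dropped)
    if (joined <= 0).any().any():
        raise ValueError("daily values must be positive for ratios")
    ratios = (
        joined["crop"] / joined["chia"]
        if orientation == "crop_over_chia"
        else joined["chia"] / joined["crop"]
    )
    return ratios.rename("ratio"), float(ratios.mean())


@dataclass(frozen=True)
class TempRegression:
    """OLS fit of daily ratios on air temperature with a slope t-test."""

    parameter: str
    crop: str
    slope: float
    intercept: float
    t_statistic: float
    p_value: float
    n_points: int


def temp_regression(
    temps: pd.Series, daily_ratios: pd.Series, parameter: str = "", crop: str = ""
) -> TempRegression:
    """Regress daily ratios on same-date air temperature.

    Ordinary least squares; the slope's significance is a two-tailed t-test
    with n - 2 degrees of freedom. Requires >= 3 matched points and
    non-degenerate temperature variance.
    """
    joined = pd.concat(
        [pd.Series(temps).rename("t"), pd.Series(daily_ratios).rename("r")], axis=1, join="inner"
    ).dropna()
    if len(joined) < 3:
        raise ValueError(f"temperature regression needs >=3 points, got {len(joined)}")
    x, y = joined["t"].to_numpy(), joined["r"].to_numpy()
    if np.var(x) == 0:
        raise ValueError("temperature series has zero variance")
    fit = sps.linregress(x, y)
    t_stat = fit.slope / fit.stderr if fit.stderr > 0 else np.inf * np.sign(fit.slope)
    return TempRegression(
        parameter=parameter,
        crop=crop,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        t_statistic=float(t_stat),
        p_value=float(fit.pvalue),
        n_points=int(len(joined)),
    )


class WaterUseComparison:
    """Cross-season water-use comparison of crops against a reference crop.

    Built from a season-summary table (one row per crop x site-season, the
    output of :func:`cropwater.seasons.season_summary_table`). ``fit()``
    computes, for every parameter in ``parameters`` and every non-reference
    crop, the per-season ratios, their cross-season mean and standard error,
    and the percent-difference rendering; optional daily series and a site
    temperature record add daily-ratio means and temperature regressions.

    Parameters
    ----------
    season_summaries:
        DataFrame with columns site_season, crop, et_total, t_total,
        et_daily_mean, t_daily_mean, wue_mean, wue_t_mean.
    reference:
        The replacement candidate every other crop is compared against
        (default ``"chia"``).
    daily:
        Optional per-crop daily flux table (columns crop, date plus flux
        columns) for daily-ratio and temperature analyses.
    temperature:
        Optional site air-temperature series indexed by date.
    """

    def __init__(
        self,
        season_summaries: pd.DataFrame,
        reference: str = "chia",
        daily: pd.DataFrame | None = None,
        temperature: pd.Series | None = None,
        parameters=tuple(PARAMETER_ORIENTATION),
    ):
        if reference not in set(season_summaries["crop"]):
            raise ValueError(f"reference crop {reference!r} absent from season summaries")
        self.season_summaries = season_summaries
        self.reference = reference
        self.daily = daily
        self.temperature = temperature
        self.parameters = tuple(parameters)

    def fit(self) -> "WaterUseComparisonResults":
        tab = self.season_summaries.set_index(["site_season", "crop"]).sort_index()
        seasons = tab.index.get_level_values("site_season").unique()
        crops = [c for c in self.season_summaries["crop"].unique() if c != self.reference]

        rows, per_season_rows = [], []
        for param in self.parameters:
            col = _PARAM_COLUMN[param]
            orient = PARAMETER_ORIENTATION[param]
            for crop in crops:
                ratios = {}
                for s in seasons:
                    try:
                        cv = tab.loc[(s, crop), col]
                        rv = tab.loc[(s, self.reference), col]
                    except KeyError:
                        continue
                    if np.isfinite(cv) and np.isfinite(rv):
                        ratios[s] = season_ratio(cv, rv, orient)
                if not ratios:
                    continue
                summ = summarize_ratios(ratios, orient)
                rows.append(
                    {
                        "parameter": param,
                        "crop": crop,
                        "orientation": orient,
                        "n_seasons": summ.n_seasons,
                        "mean_ratio": summ.mean,
                        "se": summ.se,
                        "percent": summ.percent,
                    }
                )
                per_season_rows += [
                    {"parameter": param, "crop": crop, "site_season": s, "ratio": r}
                    for s, r in ratios.items()
                ]

        regressions = self._regressions() if self.daily is not None and self.temperature is not None else []
        return WaterUseComparisonResults(
            model=self,
            ratio_table=pd.DataFrame(rows),
            season_ratios=pd.DataFrame(per_season_rows),
            regressions=pd.DataFrame([vars(r) for r in regressions]),
        )

    def _regressions(self) -> list[TempRegression]:
        out = []
        daily_params = {"ET_daily": "et", "T_daily": "transpiration"}
        ref_daily = self.daily[self.daily["crop"] == self.reference]
        temps = pd.Series(self.temperature)
        temps.index = pd.to_datetime(temps.index)
        for param, col in daily_params.items():
            if col not in self.daily.columns:
                continue
            ref = ref_daily.groupby("date")[col].mean()
            for crop in self.daily["crop"].unique():
                if crop == self.reference:
                    continue
                series = self.daily[self.daily["crop"] == crop].groupby("date")[col].mean()
                try:
                    ratios, _ = daily_ratio_series(series, ref, PARAMETER_ORIENTATION[param])
                    out.append(temp_regression(temps, ratios, parameter=param, crop=crop))
                except ValueError as err:
                    log.info("temperature regression skipped for %s/%s: %s", param, crop, err)
        return out


@dataclass
class WaterUseComparisonResults:
    """Fitted comparison: ratio estimates, uncertainties and diagnostics."""

    model: WaterUseComparison
    ratio_table: pd.DataFrame  # parameter, crop, orientation, n_seasons, mean_ratio, se, percent
    season_ratios: pd.DataFrame  # per-season ratios behind each estimate
    regressions: pd.DataFrame  # temperature regressions (may be empty)

    def summary(self) -> str:
        """Plain-text report of ratios, standard errors and percent renderings."""
        ref = self.model.reference
        lines = [
            f"Water-use comparison vs reference crop {ref!r}",
            f"{'parameter':<10} {'crop':<10} {'orient':<15} {'n':>2} "
            f"{'ratio':>8} {'SE':>7} {'percent':>8}",
        ]
        for _, r in self.ratio_table.iterrows():
            se = f"{r.se:.3f}" if np.isfinite(r.se) else "   n/a"
            lines.append(
                f"{r.parameter:<10} {r.crop:<10} {r.orientation:<15} {r.n_seasons:>2d} "
                f"{r.mean_ratio:>8.4f} {se:>7} {r.percent:>7.1f}%"
            )
        if len(self.regressions):
            lines.append("")
            lines.append("Temperature response of daily ratios (OLS, two-tailed t-test):")
            for _, g in self.regressions.iterrows():
                lines.append(
                    f"  {g.parameter:<9} {g.crop:<10} slope={g.slope:+.4f} "
                    f"t={g.t_statistic:+.2f} p={g.p_value:.3g} (n={g.n_points})"
                )
        return "\n".join(lines)

    def plot_ratios(self, parameter: str | None = None, ax=None):
        """Bar chart of mean ratios with standard-error bars."""
        import matplotlib.pyplot as plt

        tab = self.ratio_table
        if parameter is not None:
            tab = tab[tab["parameter"] == parameter]
        if ax is None:
            _, ax = plt.subplots()
        labels = tab["parameter"] + "\n" + tab["crop"]
        ax.bar(labels, tab["mean_ratio"], yerr=tab["se"].fillna(0.0), capsize=3)
        ax.axhline(1.0, color="k", lw=0.8)
        ax.set_ylabel("mean cross-season ratio")
        return ax
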