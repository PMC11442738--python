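"""Regional water-savings projection and replacement economics.

Per-hectare seasonal water use scaled by a region's cultivated area gives a
regional seasonal total; replacing a fraction w of that area with a crop that
uses 1/R as much water saves ``w x total x (1 - 1/R)`` liters. Savings are
projected under the minimum, mean and maximum cross-season ratio, may be
negative when R < 1 (the replacement uses more water), and can be expressed
as annual-household equivalents.

Economics: each crop's gross income per hectare is a (yield x price) range;
the water saved per hectare times an agricultural water price is a credit.
Scenarios are built adversarially — the best case for conversion pairs the
replacement crop's highest gross with the incumbent's lowest and the largest
water credit, the worst case the reverse, and the mean case uses range
midpoints — so the three deltas bracket the plausible change in per-hectare
profit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "regional_consumption",
    "savings_from_ratio",
    "savings_from_per_ha",
    "household_equivalent",
    "savings_table",
    "CropEconomics",
    "EconomicScenario",
    "economic_scenarios",
    "HOUSEHOLD_ANNUAL_USE_L",
]

#: annual water consumption of one household, liters. Derived constant:
#: back-computed from the pairing of 184.6 million liters of savings with
#: 1,300 households (184,600,000 / 1,300 = 142,000), not an independently
#: sourced figure. Configurable wherever it is used.
HOUSEHOLD_ANNUAL_USE_L = 142_000.0


def regional_consumption(per_ha_season_total: float, area_ha: float) -> float:
    """Seasonal water use of a whole region: per-hectare total x area (L)."""
    if per_ha_season_total < 0 or area_ha < 0:
        raise ValueError("consumption inputs must be nonnegative")
    return per_ha_season_total * area_ha


def savings_from_ratio(regional_total: float, ratio: float, weight: float) -> float:
    """Liters saved by replacing a fraction of a region's crop.

    ``weight x regional_total x (1 - 1/ratio)``: converting weight w of the
    area removes w x total of the crop's use and adds back w x total / R of
    replacement use. Negative when R < 1 (the replacement uses more water);
    negative savings are reported, never clamped.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("replacement weight must lie in [0, 1]")
    return weight * regional_total * (1.0 - 1.0 / ratio)


def savings_from_per_ha(per_ha_savings: float, area_ha: float, weight: float) -> float:
    """Liters saved from a per-hectare savings figure: w x area x per-ha."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("replacement weight must lie in [0, 1]")
    return weight * area_ha * per_ha_savings


def household_equivalent(
    savings_liters: float, annual_household_use_liters: float = HOUSEHOLD_ANNUAL_USE_L
) -> int:
    """Whole households whose annual use equals the savings (floor)."""
    if annual_household_use_liters <= 0:
        raise ValueError("annual household use must be positive")
    return int(math.floor(savings_liters / annual_household_use_liters))


def savings_table(
    inventory: pd.DataFrame,
    per_ha_totals: dict,
    ratio_cases: dict,
    weights=(0.1, 0.25, 0.5, 1.0),
    basis: str = "ET",
) -> pd.DataFrame:
    """Projected savings per crop x ratio case x replacement weight.

    Parameters
    ----------
    inventory:
        DataFrame with columns crop, area_ha (cultivated area inside the
        viability region).
    per_ha_totals:
        crop -> per-hectare seasonal water total (L ha^-1 season^-1) on the
        chosen basis (ET or transpiration).
    ratio_cases:
        crop -> {"min": R, "mean": R, "max": R} cross-season crop/chia
        ratios.
    """
    rows = []
    for _, inv in inventory.iterrows():
        crop, area = inv["crop"], float(inv["area_ha"])
        if crop not in per_ha_totals or crop not in ratio_cases:
            continue
        total = regional_consumption(per_ha_totals[crop], area)
        for case, ratio in ratio_cases[crop].items():
            for w in weights:
                saved = savings_from_ratio(total, ratio, w)
                rows.append(
                    {
                        "crop": crop,
                        "basis": basis,
                        "ratio_case": case,
                        "weight": w,
                        "area_ha": area,
                        "per_ha_savings": per_ha_totals[crop] * (1.0 - 1.0 / ratio),
                        "total_savings_l": saved,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CropEconomics:
    """Per-hectare yield and price ranges for one crop."""

    crop: str
    yield_min_t_ha: float
    yield_max_t_ha: float
    price_min_per_t: float
    price_max_per_t: float

    def __post_init__(self) -> None:
        if self.yield_min_t_ha > self.yield_max_t_ha or self.price_min_per_t > self.price_max_per_t:
            raise ValueError(f"{self.crop}: range minima must not exceed maxima")
        if min(self.yield_min_t_ha, self.price_min_per_t) < 0:
            raise ValueError(f"{self.crop}: ranges must be nonnegative")

    @property
    def gross_min(self) -> float:
        return self.yield_min_t_ha * self.price_min_per_t

    @property
    def gross_max(self) -> float:
        return self.yield_max_t_ha * self.price_max_per_t

    @property
    def gross_mid(self) -> float:
        return (
            (self.yield_min_t_ha + self.yield_max_t_ha)
            / 2.0
            * (self.price_min_per_t + self.price_max_per_t)
            / 2.0
        )


@dataclass(frozen=True)
class EconomicScenario:
    """Bracketed per-hectare profit change when replacing a crop."""

    crop: str
    delta_worst: float
    delta_mean: float
    delta_best: float

    def __post_init__(self) -> None:
        if not self.delta_worst <= self.delta_mean <= self.delta_best:
            raise ValueError("scenario deltas must be ordered worst <= mean <= best")

    def weighted_totals(self, area_ha: float, weights=(0.1, 0.25, 0.5, 1.0)) -> pd.DataFrame:
        rows = [
            {
                "crop": self.crop,
                "weight": w,
                "total_worst": self.delta_worst * w * area_ha,
                "total_mean": self.delta_mean * w * area_ha,
                "total_best": self.delta_best * w * area_ha,
            }
            for w in weights
        ]
        return pd.DataFrame(rows)


def economic_scenarios(
    crop: CropEconomics,
    replacement: CropEconomics,
    water_price_per_l: float,
    savings_range_l_ha,
) -> EconomicScenario:
    """Worst/mean/best per-hectare profit change for converting to the
    replacement crop.

    ``savings_range_l_ha`` is (min, mean, max) water savings per hectare per
    season; each times the water price is an irrigation-cost credit. The best
    case pairs the replacement's maximum gross with the incumbent crop's
    minimum and the largest credit; the worst case is the mirror image; the
    mean case uses range midpoints throughout.
    """
    if water_price_per_l < 0:
        raise ValueError("water price must be nonnegative")
    s_min, s_mean, s_max = savings_range_l_ha
    if not s_min <= s_mean <= s_max:
        raise ValueError("savings range must be ordered min <= mean <= max")
    credit_min, credit_mean, credit_max = (
        s_min * water_price_per_l,
        s_mean * water_price_per_l,
        s_max * water_price_per_l,
    )
    return EconomicScenario(
        crop=crop.crop,
        delta_worst=replacement.gross_min - crop.gross_max + credit_min,
        delta_mean=replacement.gross_mid - crop.gross_mid + credit_mean,
        delta_best=replacement.gross_max - crop.gross_min + credit_max,
    )
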