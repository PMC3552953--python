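"""Time/cost model for on-ground, remote-imagery, and combined surveys.

The on-ground survey drives every drivable road (paved and unpaved) at a
mean speed (default 30 km/h) at a fuel cost per km (default 0.19 euro);
remote imagery inspection costs screen time but no money.  Per-square
bookkeeping normalises times and costs by the surveyed (viewshed) area,
and combined-survey savings come from letting the remote method cover the
area coincident with the on-ground viewshed.

Travel to and from the survey squares is deliberately excluded, so the
savings reported here are conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, InvalidInputError, UndefinedRatioError

__all__ = [
    "CostParams",
    "SquareMetrics",
    "ground_time",
    "ground_cost",
    "per_area_rate",
    "coincident_fraction",
    "combined_savings",
    "wilcoxon_signed_rank",
    "paired_t",
]


@dataclass(frozen=True)
class CostParams:
    ground_speed_kmh: float = 30.0   # mean driving speed on survey roads
    euro_per_km: float = 0.19        # fuel cost per km driven
    remote_money_cost: float = 0.0   # per km^2; imagery inspection is free

    def __post_init__(self) -> None:
        if not self.ground_speed_kmh > 0:
            raise InvalidInputError("ground_speed_kmh must be > 0")
        if self.euro_per_km < 0:
            raise InvalidInputError("euro_per_km must be >= 0")


@dataclass
class SquareMetrics:
    """Per-survey-square bookkeeping (areas km^2, lengths km, times min)."""

    square_id: str
    area_km2: float
    road_km_ground: float          # drivable length, paved + unpaved
    viewshed_ground_km2: float
    viewshed_remote_km2: float
    time_ground_min: float = math.nan
    time_remote_min: float = math.nan

    def __post_init__(self) -> None:
        if self.viewshed_ground_km2 > self.area_km2 + 1e-9 or self.viewshed_remote_km2 > self.area_km2 + 1e-9:
            raise InvalidInputError(f"square {self.square_id}: viewshed exceeds square area")
        if min(self.viewshed_ground_km2, self.viewshed_remote_km2) < 0:
            raise InvalidInputError(f"square {self.square_id}: negative viewshed")


def ground_time(road_km: float, params: CostParams) -> float:
    """Minutes to drive ``road_km`` at the configured mean speed."""
    if road_km < 0:
        raise InvalidInputError("road_km must be >= 0")
    return 60.0 * road_km / params.ground_speed_kmh


def ground_cost(road_km: float, params: CostParams) -> float:
    """Euros of fuel to drive ``road_km``."""
    if road_km < 0:
        raise InvalidInputError("road_km must be >= 0")
    return road_km * params.euro_per_km


def per_area_rate(total: float, viewshed_km2: float) -> float:
    """Normalise a total (minutes or euros) by surveyed area (km^2)."""
    if viewshed_km2 <= 0:
        raise UndefinedRatioError("zero or negative viewshed area")
    return total / viewshed_km2


def coincident_fraction(sq: SquareMetrics) -> float:
    """Share of the on-ground viewshed also covered by the remote viewshed."""
    if sq.viewshed_ground_km2 <= 0:
        raise UndefinedRatioError(f"square {sq.square_id}: zero ground viewshed")
    f = sq.viewshed_remote_km2 / sq.viewshed_ground_km2
    if f > 1 + 1e-9:
        raise InvalidInputError(
            f"square {sq.square_id}: remote viewshed exceeds ground viewshed (f={f:.3f})"
        )
    return min(f, 1.0)


def combined_savings(sq: SquareMetrics, params: CostParams) -> dict:
    """Time and money saved by surveying the coincident area remotely.

    With f the coincident fraction, t_g/t_r the per-km^2 time rates and
    c_g the per-km^2 money rate of the ground survey:

        time_saved = f * viewshed_ground * (t_g - t_r)
        cost_saved = f * viewshed_ground * c_g        (remote money cost 0)
        pct_time   = 100 * time_saved / (viewshed_ground * t_g)
        pct_cost   = 100 * f

    A remote method slower than the ground one yields a negative time
    saving with ``remote_slower=True`` — possible, not an error.
    """
    f = coincident_fraction(sq)
    t_g = per_area_rate(sq.time_ground_min, sq.viewshed_ground_km2)
    t_r = per_area_rate(sq.time_remote_min, sq.viewshed_remote_km2) if sq.viewshed_remote_km2 > 0 else 0.0
    c_g = per_area_rate(ground_cost(sq.road_km_ground, params), sq.viewshed_ground_km2)
    time_saved = f * sq.viewshed_ground_km2 * (t_g - t_r)
    cost_saved = f * sq.viewshed_ground_km2 * (c_g - params.remote_money_cost)
    total_time_ground = sq.viewshed_ground_km2 * t_g
    return {
        "time_saved_min": time_saved,
        "cost_saved_eur": cost_saved,
        "pct_time": 100.0 * time_saved / total_time_ground if total_time_ground > 0 else 0.0,
        "pct_cost": 100.0 * f if params.remote_money_cost == 0 else
                    100.0 * cost_saved / (sq.viewshed_ground_km2 * c_g),
        "remote_slower": t_r > t_g,
    }


# -- paired tests -----------------------------------------------------------

def wilcoxon_signed_rank(x, y) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the null distribution is exact for
    n <= 25 pairs.  By convention identical samples (all differences zero)
    return V = 0 with p = 1 rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidInputError("need two equal-length 1-D samples with n >= 2")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return {"V": 0.0, "p": 1.0}
    method = "exact" if nz.size <= 25 else "auto"
    res = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
    return {"V": float(res.statistic), "p": float(res.pvalue)}


def paired_t(x, y) -> dict:
    """Two-sided paired t test; antisymmetric in argument order."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidInputError("need two equal-length 1-D samples with n >= 2")
    if np.ptp(x - y) == 0:
        raise DegenerateSampleError("paired differences have zero variance")
    res = stats.ttest_rel(x, y)
    return {"t": float(res.statistic), "p": float(res.pvalue)}
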