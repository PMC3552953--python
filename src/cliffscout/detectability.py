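"""Distance-to-road analysis of remote identifiability and feature detection.

Whether a cliff can be identified in street-level imagery is limited by how
far it sits from the nearest imagery-covered road: identified cliffs lie
systematically nearer covered roads than unidentified ones, and beyond
roughly a kilometre identification becomes unlikely.  This module provides
the distance computations, the summary-statistic tests used to compare
identified and unidentified groups, detection-rate arithmetic, and the
per-feature (white excrement spots, caves, vegetation) detection table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point

from .cliff_classifier import CliffSite
from .errors import DegenerateSampleError, InfeasibleSamplingError, InvalidInputError
from .roads import RoadNetwork
from .terrain import GridPoint

__all__ = [
    "nearest_covered_road_distance",
    "WelchT",
    "welch_t_from_summaries",
    "welch_t_from_samples",
    "DetectionRate",
    "detection_rate",
    "chi_square_2x2",
    "distance_summary",
    "feature_detection_table",
    "identification_summary",
    "fit_logistic_identification",
]

FEATURES = {
    "white_spots": ("has_white_spots", "remote_white_spots"),
    "caves": ("has_cave", "remote_cave"),
    "vegetation": ("has_vegetation", "remote_vegetation"),
}


def nearest_covered_road_distance(p: GridPoint, roads: RoadNetwork) -> float:
    """Minimum Euclidean distance from ``p`` to any imagery-covered polyline."""
    covered = roads.select(covered_only=True)
    if not covered:
        raise InfeasibleSamplingError("road network has no imagery-covered polylines")
    pt = Point(p.x, p.y)
    return min(r.line.distance(pt) for r in covered)


@dataclass(frozen=True)
class WelchT:
    """Welch t statistic; ``rounded`` is the 2-decimal value as printed."""

    t: float
    rounded: float
    df: float | None = None
    p: float | None = None


def welch_t_from_summaries(
    mean1: float, se1: float, mean2: float, se2: float,
    n1: int | None = None, n2: int | None = None,
) -> WelchT:
    """Welch t from group means and standard errors.

    t = |mean1 - mean2| / sqrt(se1^2 + se2^2).  When group sizes are given,
    Welch-Satterthwaite degrees of freedom and a two-sided p-value are
    attached as secondary outputs.
    """
    if se1 <= 0 or se2 <= 0:
        raise InvalidInputError("standard errors must be > 0")
    t = abs(mean1 - mean2) / np.hypot(se1, se2)
    df = p = None
    if n1 is not None and n2 is not None:
        df = (se1**2 + se2**2) ** 2 / (se1**4 / (n1 - 1) + se2**4 / (n2 - 1))
        p = 2 * stats.t.sf(t, df)
    return WelchT(t=float(t), rounded=round(float(t), 2), df=df, p=p)


def welch_t_from_samples(x, y) -> WelchT:
    """Welch t from raw samples (means/SEs computed then delegated)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidInputError("need at least 2 observations per group")
    se1 = x.std(ddof=1) / np.sqrt(x.size)
    se2 = y.std(ddof=1) / np.sqrt(y.size)
    if se1 == 0 or se2 == 0:
        raise DegenerateSampleError("a group has zero variance")
    return welch_t_from_summaries(x.mean(), se1, y.mean(), se2, x.size, y.size)


@dataclass(frozen=True)
class DetectionRate:
    exact: float    # percentage, unrounded
    rounded: int    # nearest-integer percentage as printed


def detection_rate(k: int, n: int) -> DetectionRate:
    """Percentage 100*k/n of ``n`` items of which ``k`` were detected."""
    if n <= 0 or not 0 <= k <= n:
        raise InvalidInputError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    pct = 100.0 * k / n
    return DetectionRate(exact=pct, rounded=int(round(pct)))


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> dict:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]].

    Optional Yates continuity correction; p from chi-square with 1 df.
    """
    if min(a, b, c, d) < 0:
        raise InvalidInputError("counts must be >= 0")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateSampleError("zero marginal in 2x2 table")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2, 0.0)
    statistic = n * num**2 / (r1 * r2 * c1 * c2)
    return {"statistic": float(statistic), "p": float(stats.chi2.sf(statistic, 1))}


def distance_summary(distances) -> dict:
    """Median and 75th percentile (linear interpolation rule)."""
    arr = np.asarray(distances, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("empty distance list")
    return {"median": float(np.percentile(arr, 50)), "p75": float(np.percentile(arr, 75))}


def feature_detection_table(sites: list[CliffSite]) -> pd.DataFrame:
    """Per-feature field counts, remote counts, and remote detection rates.

    ``remote_pct`` is the detection rate of remotely seen features among
    all field-flagged sites (identified or not); undefined (NaN) when no
    site carries the field flag.
    """
    rows = []
    for name, (field_attr, remote_attr) in FEATURES.items():
        field_n = sum(getattr(s, field_attr) for s in sites)
        remote_n = sum(getattr(s, field_attr) and getattr(s, remote_attr) for s in sites)
        if field_n > 0:
            rate = detection_rate(remote_n, field_n)
            exact, rounded = rate.exact, rate.rounded
        else:
            exact, rounded = float("nan"), float("nan")
        rows.append({"feature": name, "field_n": field_n, "remote_n": remote_n,
                     "remote_pct_exact": exact, "remote_pct": rounded})
    return pd.DataFrame(rows).set_index("feature")


def identification_summary(sites: list[CliffSite]) -> pd.DataFrame:
    """Identified-cliff counts by species group (total / griffon / egyptian / both)."""
    groups = {
        "total": lambda s: True,
        "griffon": lambda s: s.occupied_by_griffon,
        "egyptian": lambda s: s.occupied_by_egyptian,
        "both_species": lambda s: s.occupied_by_griffon and s.occupied_by_egyptian,
    }
    rows = []
    for name, pred in groups.items():
        grp = [s for s in sites if pred(s)]
        n = len(grp)
        k = sum(s.remote_identified for s in grp)
        pct = detection_rate(k, n).rounded if n else float("nan")
        rows.append({"group": name, "n_cliffs": n, "identified": k, "identified_pct": pct})
    return pd.DataFrame(rows).set_index("group")


def fit_logistic_identification(distances, identified) -> dict:
    """Maximum-likelihood logistic fit of identification vs distance.

    Fits P(identified) = logistic((d50 - d) / s) via a plain logistic
    regression on distance and reparameterises: d50 = -b0/b1, s = -1/b1.
    """
    import statsmodels.api as sm

    d = np.asarray(distances, dtype=float)
    y = np.asarray(identified, dtype=float)
    if d.size != y.size or d.size < 10:
        raise InvalidInputError("need matched distance/outcome arrays, n >= 10")
    X = sm.add_constant(d)
    fit = sm.Logit(y, X).fit(disp=0)
    b0, b1 = fit.params
    if b1 >= 0:
        raise DegenerateSampleError("identification does not decay with distance")
    return {"d50": float(-b0 / b1), "scale": float(-1.0 / b1),
            "intercept": float(b0), "slope": float(b1)}
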