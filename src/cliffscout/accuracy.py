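"""Ground-truth sampling and thematic-map accuracy assessment.

All metrics derive from a 2x2 confusion matrix of reference (field) class
against mapped class for the cliff / non-cliff dichotomy.  Two conventions
are implemented for user's accuracy and commission error:

* ``map``-relative (the textbook definition): commission = fp / (tp + fp),
  the share of map-cliff points that are not really cliff;
* ``reference``-relative: commission = fp / (fp + tn), the share of
  reference non-cliff points mis-mapped as cliff.

Published cliff-mapping accuracy tables in this line of work pair a user's
accuracy of 90 with a commission error of 0.10 for a matrix with tp=49,
fp=5, tn=45 — figures only consistent with the reference-relative
convention, which is therefore the default here; both are available and
labelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ExtentError,
    InfeasibleSamplingError,
    InvalidInputError,
    UndefinedRatioError,
)
from .terrain import GridPoint, RasterGrid

__all__ = [
    "CLIFF", "NON_CLIFF",
    "GroundTruthPoint",
    "ConfusionMatrix2x2",
    "sample_ground_truth",
    "evaluate",
    "overall_accuracy",
    "producers_accuracy",
    "users_accuracy",
    "omission_error_rate",
    "commission_error_rate",
    "cohens_kappa",
]

CLIFF = "cliff"
NON_CLIFF = "non-cliff"
MAP_RELATIVE = "map"
REFERENCE_RELATIVE = "reference"


@dataclass(frozen=True)
class GroundTruthPoint:
    position: GridPoint
    true_class: str
    stratum: str

    def __post_init__(self) -> None:
        if self.true_class not in (CLIFF, NON_CLIFF):
            raise InvalidInputError(f"unknown class {self.true_class!r}")


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts: tp (true cliff, mapped cliff), fn, fp, tn."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise InvalidInputError("confusion counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


# -- sampling ---------------------------------------------------------------

def _apportion(n: int, k: int, start: int) -> list[int]:
    """Largest-remainder apportionment of ``n`` among ``k`` equal strata.

    With equal quotas all remainders tie; the ``n % k`` extra units go to
    consecutive strata cyclically from ``start``, so two calls with
    different starts spread their extras over disjoint strata.
    """
    base, extra = divmod(n, k)
    counts = [base] * k
    for i in range(extra):
        counts[(start + i) % k] += 1
    return counts


def sample_ground_truth(
    grid: RasterGrid,
    region_mask: np.ndarray,
    truth_mask: np.ndarray,
    n_cliff: int,
    n_noncliff: int,
    strata: list[np.ndarray],
    seed: int,
) -> list[GroundTruthPoint]:
    """Stratified random ground-truth points, without replacement.

    ``n_cliff`` points on true cliff cells and ``n_noncliff`` on true
    non-cliff cells, each class allocated across the strata as evenly as
    possible (per-class counts differing by at most one, with the two
    classes' remainder points placed on disjoint strata so the combined
    per-stratum totals also differ by at most one).  Deterministic given
    ``seed``.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    k = len(strata)
    if k == 0:
        raise InvalidInputError("need at least one stratum")
    cliff_counts = _apportion(n_cliff, k, start=0)
    non_counts = _apportion(n_noncliff, k, start=n_cliff % k)
    points: list[GroundTruthPoint] = []
    for idx, stratum in enumerate(strata):
        stratum = np.asarray(stratum, dtype=bool)
        for cls, mask, need in (
            (CLIFF, truth_mask, cliff_counts[idx]),
            (NON_CLIFF, ~truth_mask, non_counts[idx]),
        ):
            cand = np.flatnonzero(region_mask & mask & stratum)
            if cand.size < need:
                raise InfeasibleSamplingError(
                    f"stratum {idx}: {cand.size} candidate {cls} cells, need {need}"
                )
            chosen = rng.choice(cand, size=need, replace=False)
            for flat in np.sort(chosen):
                r, c = np.unravel_index(flat, region_mask.shape)
                points.append(GroundTruthPoint(
                    position=grid.cell_center(int(r), int(c)),
                    true_class=cls,
                    stratum=str(idx),
                ))
    return points


def evaluate(map_grid, points: list[GroundTruthPoint]) -> ConfusionMatrix2x2:
    """Confusion matrix of a cliff map against ground-truth points."""
    grid = getattr(map_grid, "grid", map_grid)  # accept CliffMap or RasterGrid
    tp = fn = fp = tn = 0
    for p in points:
        r, c = grid.point_to_cell(p.position)
        mapped_cliff = bool(grid.values[r, c])
        if p.true_class == CLIFF:
            if mapped_cliff:
                tp += 1
            else:
                fn += 1
        else:
            if mapped_cliff:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix2x2(tp=tp, fn=fn, fp=fp, tn=tn)


# -- metrics ----------------------------------------------------------------

def overall_accuracy(cm: ConfusionMatrix2x2) -> float:
    """Percentage of points classified correctly."""
    if cm.n == 0:
        raise UndefinedRatioError("empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.n


def producers_accuracy(cm: ConfusionMatrix2x2, cls: str = CLIFF) -> float:
    """Percentage of reference points of ``cls`` mapped to ``cls``."""
    if cls == CLIFF:
        denom, num = cm.tp + cm.fn, cm.tp
    elif cls == NON_CLIFF:
        denom, num = cm.fp + cm.tn, cm.tn
    else:
        raise InvalidInputError(f"unknown class {cls!r}")
    if denom == 0:
        raise UndefinedRatioError(f"no reference points of class {cls!r}")
    return 100.0 * num / denom


def users_accuracy(
    cm: ConfusionMatrix2x2, cls: str = CLIFF, convention: str = REFERENCE_RELATIVE
) -> float:
    """Percentage of ``cls`` map points that are really ``cls``.

    ``map`` convention: 100 * tp / (tp + fp) for cliff (the textbook rule).
    ``reference`` convention: 100 * (1 - fp / (fp + tn)) — the complement of
    the reference-relative commission error; the package default (see
    module docstring).
    """
    if cls == CLIFF:
        if convention == MAP_RELATIVE:
            denom = cm.tp + cm.fp
            if denom == 0:
                raise UndefinedRatioError("no mapped cliff points")
            return 100.0 * cm.tp / denom
        if convention == REFERENCE_RELATIVE:
            return 100.0 * (1.0 - commission_error_rate(cm, REFERENCE_RELATIVE))
    elif cls == NON_CLIFF:
        if convention == MAP_RELATIVE:
            denom = cm.fn + cm.tn
            if denom == 0:
                raise UndefinedRatioError("no mapped non-cliff points")
            return 100.0 * cm.tn / denom
        if convention == REFERENCE_RELATIVE:
            denom = cm.tp + cm.fn
            if denom == 0:
                raise UndefinedRatioError("no reference cliff points")
            return 100.0 * (1.0 - cm.fn / denom)
    else:
        raise InvalidInputError(f"unknown class {cls!r}")
    raise InvalidInputError(f"unknown convention {convention!r}")


def omission_error_rate(cm: ConfusionMatrix2x2) -> float:
    """False-negative rate fn / (tp + fn), in [0, 1]."""
    denom = cm.tp + cm.fn
    if denom == 0:
        raise UndefinedRatioError("no reference cliff points")
    return cm.fn / denom


def commission_error_rate(
    cm: ConfusionMatrix2x2, convention: str = REFERENCE_RELATIVE
) -> float:
    """False-positive rate, in [0, 1].

    ``reference``: fp / (fp + tn) (default); ``map``: fp / (tp + fp).
    """
    if convention == REFERENCE_RELATIVE:
        denom = cm.fp + cm.tn
    elif convention == MAP_RELATIVE:
        denom = cm.tp + cm.fp
    else:
        raise InvalidInputError(f"unknown convention {convention!r}")
    if denom == 0:
        raise UndefinedRatioError("empty denominator for commission error")
    return cm.fp / denom


def cohens_kappa(cm: ConfusionMatrix2x2) -> float:
    """Chance-corrected agreement (po - pe) / (1 - pe).

    po = (tp + tn) / N; pe from the marginal products.  With balanced
    reference classes (tp + fn == fp + tn) pe is exactly 1/2, so
    kappa == 2 * po - 1.
    """
    n = cm.n
    if n == 0:
        raise UndefinedRatioError("empty confusion matrix")
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    if pe == 1.0:
        if po == 1.0:
            return 1.0
        raise UndefinedRatioError("chance agreement is 1 with imperfect observed agreement")
    return (po - pe) / (1.0 - pe)
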