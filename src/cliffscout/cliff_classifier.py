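"""Slope-threshold cliff classification.

Thresholds are derived from the slopes observed at occupied nesting cliffs:
the sample minimum (Smin) and its 25th and 50th percentiles (S25th, S50th).
Thresholding the slope raster at each value yields three nested candidate
cliff maps — the lower the threshold, the more inclusive the map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .terrain import GridPoint, RasterGrid, SlopeGrid

__all__ = [
    "CliffSite",
    "SlopeThresholds",
    "CliffMap",
    "occupied_slope_sample",
    "thresholds_from_sample",
    "classify",
    "read_sites_csv",
    "write_sites_csv",
]

LIMESTONE = "limestone"
NON_LIMESTONE = "non-limestone"


@dataclass
class CliffSite:
    """A nesting or candidate cliff location with field and remote flags.

    Field flags (``has_*``) come from on-ground surveys; remote flags
    (``remote_*``) may only be set on sites that were remotely identified.
    """

    id: str
    position: GridPoint
    occupied_by_griffon: bool = False
    occupied_by_egyptian: bool = False
    has_white_spots: bool = False
    has_cave: bool = False
    has_vegetation: bool = False
    substrate: str = LIMESTONE
    remote_identified: bool = False
    remote_white_spots: bool = False
    remote_cave: bool = False
    remote_vegetation: bool = False

    def __post_init__(self) -> None:
        if not self.remote_identified and (
            self.remote_white_spots or self.remote_cave or self.remote_vegetation
        ):
            raise InvalidInputError(
                f"site {self.id}: remote feature flags require remote_identified"
            )


@dataclass(frozen=True)
class SlopeThresholds:
    """Minimum / 25th-percentile / 50th-percentile occupied-cliff gradients."""

    s_min: float
    s_25: float
    s_50: float

    def __post_init__(self) -> None:
        if not (self.s_min <= self.s_25 <= self.s_50):
            raise InvalidInputError(
                f"thresholds must be ordered: {self.s_min} <= {self.s_25} <= {self.s_50}"
            )

    def as_dict(self) -> dict[str, float]:
        return {"s_min": self.s_min, "s_25": self.s_25, "s_50": self.s_50}


@dataclass
class CliffMap:
    """Binary candidate-cliff raster plus a validity mask.

    ``grid.values`` is boolean (cliff / non-cliff); ``valid`` marks cells
    where the source slope was defined — nodata slope cells are classified
    non-cliff but flagged invalid here.
    """

    grid: RasterGrid
    valid: np.ndarray
    threshold: float


def occupied_slope_sample(slopes: SlopeGrid, sites: list[CliffSite]) -> list[float]:
    """Slope at each site's containing cell, order-stable by site id.

    The slope is read from the single containing cell, no neighbourhood
    statistic (a 3x3 maximum is a conceivable alternative but the point
    reading is the simplest faithful choice).
    """
    out = []
    valid = slopes.mask
    for site in sorted(sites, key=lambda s: s.id):
        r, c = slopes.point_to_cell(site.position)
        if not valid[r, c]:
            raise InvalidInputError(f"site {site.id} lies on nodata slope")
        out.append(float(slopes.values[r, c]))
    return out


def thresholds_from_sample(sample: list[float]) -> SlopeThresholds:
    """Smin/S25th/S50th from an occupied-cliff slope sample.

    Percentiles use linear interpolation between closest order statistics
    (the common statistical-software default).
    """
    if len(sample) == 0:
        raise InvalidInputError("empty slope sample")
    arr = np.asarray(sample, dtype=float)
    return SlopeThresholds(
        s_min=float(arr.min()),
        s_25=float(np.percentile(arr, 25)),
        s_50=float(np.percentile(arr, 50)),
    )


def classify(slopes: SlopeGrid, threshold: float) -> CliffMap:
    """Cells with slope >= threshold are cliff.

    ``>=`` (not ``>``) so that the occupied cliff holding the sample
    minimum is itself captured by the Smin map.  Nodata slope cells are
    non-cliff and marked invalid in the companion mask.
    """
    if threshold < 0:
        raise InvalidInputError(f"threshold must be >= 0, got {threshold}")
    valid = slopes.mask
    cliff = np.zeros(slopes.values.shape, dtype=bool)
    cliff[valid] = slopes.values[valid] >= threshold
    return CliffMap(grid=slopes.like(cliff, nodata=None), valid=valid, threshold=threshold)


# -- site table I/O ---------------------------------------------------------

_BOOL_COLS = [
    "occupied_by_griffon", "occupied_by_egyptian",
    "has_white_spots", "has_cave", "has_vegetation",
    "remote_identified", "remote_white_spots", "remote_cave", "remote_vegetation",
]


def write_sites_csv(sites: list[CliffSite], path: str | Path) -> None:
    rows = []
    for s in sites:
        row = {"id": s.id, "x": s.position.x, "y": s.position.y, "substrate": s.substrate}
        row.update({col: getattr(s, col) for col in _BOOL_COLS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sites_csv(path: str | Path) -> list[CliffSite]:
    df = pd.read_csv(path)
    sites = []
    for _, row in df.iterrows():
        kwargs = {col: bool(row[col]) for col in _BOOL_COLS if col in df.columns}
        sites.append(CliffSite(
            id=str(row["id"]),
            position=GridPoint(float(row["x"]), float(row["y"])),
            substrate=row.get("substrate", LIMESTONE),
            **kwargs,
        ))
    return sites
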