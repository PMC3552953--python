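"""Road network data model and GeoJSON / CSV I/O.

A :class:`RoadNetwork` is a flat set of polylines, each carrying a surface
class (``paved`` / ``unpaved``) and an imagery-coverage flag marking the
stretches for which street-level imagery exists.  Covered roads are always
paved: imagery vehicles do not drive dirt tracks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .errors import InvalidInputError

__all__ = ["Road", "RoadNetwork", "read_roads_geojson", "write_roads_geojson",
           "read_roads_csv", "write_roads_csv"]

PAVED = "paved"
UNPAVED = "unpaved"


@dataclass
class Road:
    """A single polyline with surface class and imagery-coverage flag."""

    road_id: str
    coords: np.ndarray  # (k, 2) vertex array, metres
    surface: str = PAVED
    covered: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] < 2 or self.coords.shape[1] != 2:
            raise InvalidInputError(f"road {self.road_id}: need a (k>=2, 2) vertex array")
        if self.surface not in (PAVED, UNPAVED):
            raise InvalidInputError(f"road {self.road_id}: unknown surface {self.surface!r}")
        if self.covered and self.surface != PAVED:
            raise InvalidInputError(f"road {self.road_id}: only paved roads can be imagery-covered")

    @property
    def line(self) -> LineString:
        return LineString(self.coords)

    @property
    def length(self) -> float:
        return float(self.line.length)


@dataclass
class RoadNetwork:
    roads: list[Road] = field(default_factory=list)

    def select(self, covered_only: bool = False, surface: str | None = None) -> list[Road]:
        out = self.roads
        if covered_only:
            out = [r for r in out if r.covered]
        if surface is not None:
            out = [r for r in out if r.surface == surface]
        return out

    def total_length(self, covered_only: bool = False, surface: str | None = None) -> float:
        return sum(r.length for r in self.select(covered_only, surface))

    def covered_fraction(self, surface: str | None = PAVED) -> float:
        """Share of (by default paved) road length that is imagery-covered."""
        total = self.total_length(surface=surface)
        if total == 0:
            return 0.0
        return self.total_length(covered_only=True, surface=surface) / total


def write_roads_geojson(net: RoadNetwork, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)] for x, y in r.coords]},
            "properties": {"road_id": r.road_id, "surface": r.surface,
                           "covered": bool(r.covered)},
        }
        for r in net.roads
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_roads_geojson(path: str | Path) -> RoadNetwork:
    doc = json.loads(Path(path).read_text())
    roads = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "LineString":
            raise InvalidInputError(f"unsupported geometry type {geom.get('type')!r}")
        props = feat.get("properties", {})
        roads.append(Road(
            road_id=str(props.get("road_id", len(roads))),
            coords=np.array(geom["coordinates"], dtype=float),
            surface=props.get("surface", PAVED),
            covered=bool(props.get("covered", False)),
        ))
    return RoadNetwork(roads)


def write_roads_csv(net: RoadNetwork, path: str | Path) -> None:
    """Long-format CSV: one row per vertex, ordered within each road."""
    rows = []
    for r in net.roads:
        for k, (x, y) in enumerate(r.coords):
            rows.append({"road_id": r.road_id, "vertex": k, "x": x, "y": y,
                         "surface": r.surface, "covered": r.covered})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_roads_csv(path: str | Path) -> RoadNetwork:
    df = pd.read_csv(path)
    roads = []
    for rid, grp in df.groupby("road_id", sort=False):
        grp = grp.sort_values("vertex")
        roads.append(Road(
            road_id=str(rid),
            coords=grp[["x", "y"]].to_numpy(),
            surface=grp["surface"].iloc[0],
            covered=bool(grp["covered"].iloc[0]),
        ))
    return RoadNetwork(roads)
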