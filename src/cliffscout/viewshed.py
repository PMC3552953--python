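"""Line-of-sight visibility from road-based observers over a DEM.

The sightline test is the classic exact ("R3"-style) profile test: the
segment from the observer's eye to the target is checked against the
terrain at every crossing with the grid lines through cell centres, with
terrain interpolated linearly between the two adjacent cell centres along
the crossed line, plus the midpoint of every crossing interval (where the
bilinear surface along the ray can bulge above its crossing values).  This
is slower than sweep approximations but directly verifiable against a
dense-ray oracle, which matters more at desk scale.

Earth curvature and refraction are deliberately ignored (sightlines here
are a few km at most), as is vegetation occlusion: this is *potential*
visibility, the quantity a GIS viewshed reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, UndefinedRatioError
from .roads import RoadNetwork
from .terrain import ElevationGrid, GridPoint, RasterGrid

__all__ = [
    "Observer",
    "VisibilityGrid",
    "observers_along_roads",
    "line_of_sight",
    "viewshed",
    "visibility_at_points",
    "visible_fraction",
]

logger = logging.getLogger(__name__)

#: Boolean raster of per-cell visibility, sharing the source DEM geometry.
VisibilityGrid = RasterGrid

DEFAULT_EYE_HEIGHT = 2.5  # m; vehicle-mounted camera height


@dataclass(frozen=True)
class Observer:
    """A viewpoint at ``eye_height`` metres above the terrain surface."""

    position: GridPoint
    eye_height: float = DEFAULT_EYE_HEIGHT

    def __post_init__(self) -> None:
        if self.eye_height < 0:
            raise InvalidInputError(f"eye_height must be >= 0, got {self.eye_height}")


def observers_along_roads(
    roads: RoadNetwork,
    spacing: float,
    covered_only: bool = False,
    eye_height: float = DEFAULT_EYE_HEIGHT,
    surface: str | None = None,
) -> list[Observer]:
    """Observers at arc-length intervals along each selected polyline.

    Both endpoints of every polyline are always included, so a spacing
    equal to the cell size guarantees no road cell is skipped.  An empty
    selection yields an empty list (logged, not an error).
    """
    if not spacing > 0:
        raise InvalidInputError(f"spacing must be > 0, got {spacing}")
    selected = roads.select(covered_only=covered_only, surface=surface)
    if not selected:
        logger.info("observers_along_roads: empty road selection")
        return []
    observers: list[Observer] = []
    for road in selected:
        line = road.line
        length = line.length
        dists = list(np.arange(0.0, length, spacing))
        if not dists or length - dists[-1] > 1e-9:
            dists.append(length)
        for d in dists:
            pt = line.interpolate(d)
            observers.append(Observer(GridPoint(pt.x, pt.y), eye_height=eye_height))
    return observers


# -- sightline core ---------------------------------------------------------

def _opaque_terrain(dem: ElevationGrid) -> np.ndarray:
    """Terrain array with nodata replaced by +inf (nodata is opaque)."""
    z = dem.values.astype(float).copy()
    if dem.nodata is not None:
        z[dem.values == dem.nodata] = np.inf
    return z


def _segment_clears(
    terrain: np.ndarray,
    g: RasterGrid,
    x0: float, y0: float, z0: float,
    x1: float, y1: float, z1: float,
) -> bool:
    """True iff the 3-D segment clears the terrain at every grid-line crossing."""
    cs = g.cell_size
    n_rows, n_cols = terrain.shape
    # fractional cell-centre coordinates (integer = on a centre line)
    cf0 = (x0 - g.origin_x) / cs - 0.5
    cf1 = (x1 - g.origin_x) / cs - 0.5
    rf0 = (g.y_top - y0) / cs - 0.5
    rf1 = (g.y_top - y1) / cs - 0.5

    ts: list[np.ndarray] = []
    heights: list[np.ndarray] = []

    if cf1 != cf0:
        lo, hi = (cf0, cf1) if cf0 < cf1 else (cf1, cf0)
        cols = np.arange(np.floor(lo) + 1, np.ceil(hi))
        cols = cols[(cols >= 0) & (cols <= n_cols - 1)]
        if cols.size:
            t = (cols - cf0) / (cf1 - cf0)
            rr = np.clip(rf0 + t * (rf1 - rf0), 0.0, n_rows - 1)
            fl = np.floor(rr).astype(int)
            ce = np.minimum(fl + 1, n_rows - 1)
            frac = rr - fl
            ci = cols.astype(int)
            heights.append(terrain[fl, ci] * (1 - frac) + terrain[ce, ci] * frac)
            ts.append(t)

    if rf1 != rf0:
        lo, hi = (rf0, rf1) if rf0 < rf1 else (rf1, rf0)
        rows = np.arange(np.floor(lo) + 1, np.ceil(hi))
        rows = rows[(rows >= 0) & (rows <= n_rows - 1)]
        if rows.size:
            t = (rows - rf0) / (rf1 - rf0)
            cc = np.clip(cf0 + t * (cf1 - cf0), 0.0, n_cols - 1)
            fl = np.floor(cc).astype(int)
            ce = np.minimum(fl + 1, n_cols - 1)
            frac = cc - fl
            ri = rows.astype(int)
            heights.append(terrain[ri, fl] * (1 - frac) + terrain[ri, ce] * frac)
            ts.append(t)

    if not ts:
        return True
    t = np.concatenate(ts)
    h = np.concatenate(heights)
    inner = (t > 1e-12) & (t < 1 - 1e-12)
    eps = 1e-9 * (1.0 + abs(z0) + abs(z1))
    if inner.any():
        sight = z0 + t[inner] * (z1 - z0)
        if np.any(h[inner] > sight + eps):
            return False
    # between consecutive crossings the bilinear surface along the ray is
    # quadratic and can bulge above its endpoint values; sample the interval
    # midpoints so grazing rays over convex cells are not missed
    tm = np.sort(np.concatenate([t[inner], [0.0, 1.0]]))
    tm = (tm[:-1] + tm[1:]) / 2
    xm = x0 + tm * (x1 - x0)
    ym = y0 + tm * (y1 - y0)
    cf = np.clip((xm - g.origin_x) / cs - 0.5, 0.0, n_cols - 1)
    rf = np.clip((g.y_top - ym) / cs - 0.5, 0.0, n_rows - 1)
    c0i = np.floor(cf).astype(int)
    r0i = np.floor(rf).astype(int)
    c1i = np.minimum(c0i + 1, n_cols - 1)
    r1i = np.minimum(r0i + 1, n_rows - 1)
    fc = cf - c0i
    fr = rf - r0i
    hm = ((terrain[r0i, c0i] * (1 - fc) + terrain[r0i, c1i] * fc) * (1 - fr)
          + (terrain[r1i, c0i] * (1 - fc) + terrain[r1i, c1i] * fc) * fr)
    sight_m = z0 + tm * (z1 - z0)
    return not np.any(hm > sight_m + eps)


def line_of_sight(
    dem: ElevationGrid,
    obs: Observer,
    target: GridPoint,
    target_height: float = 0.0,
    _terrain: np.ndarray | None = None,
) -> bool:
    """Is ``target`` (at ``target_height`` m above ground) visible from ``obs``?

    A target in the observer's own cell is always visible.  Nodata terrain
    under either endpoint is an error; intermediate nodata cells are treated
    as opaque.
    """
    r0, c0 = dem.point_to_cell(obs.position)
    r1, c1 = dem.point_to_cell(target)
    valid = dem.mask
    if not valid[r0, c0]:
        raise InvalidInputError(f"observer cell ({r0}, {c0}) is nodata terrain")
    if not valid[r1, c1]:
        raise InvalidInputError(f"target cell ({r1}, {c1}) is nodata terrain")
    if (r0, c0) == (r1, c1):
        return True
    terrain = _terrain if _terrain is not None else _opaque_terrain(dem)
    z0 = float(dem.values[r0, c0]) + obs.eye_height
    z1 = float(dem.values[r1, c1]) + target_height
    return _segment_clears(terrain, dem,
                           obs.position.x, obs.position.y, z0,
                           target.x, target.y, z1)


# -- viewshed ---------------------------------------------------------------

def _prepare_observers(dem: ElevationGrid, observers: list[Observer]):
    xs = np.array([o.position.x for o in observers])
    ys = np.array([o.position.y for o in observers])
    cells = [dem.point_to_cell(o.position) for o in observers]
    valid = dem.mask
    for (r, c), o in zip(cells, observers):
        if not valid[r, c]:
            raise InvalidInputError(f"observer at ({o.position.x}, {o.position.y}) on nodata terrain")
    z = np.array([dem.values[r, c] + o.eye_height for (r, c), o in zip(cells, observers)])
    return xs, ys, cells, z


def _visible_from_any(
    terrain: np.ndarray,
    dem: ElevationGrid,
    target: GridPoint,
    r: int, c: int,
    ox: np.ndarray, oy: np.ndarray,
    ocells: list[tuple[int, int]],
    oz: np.ndarray,
    target_height: float,
    max_d2: float,
) -> bool:
    z1 = float(dem.values[r, c]) + target_height
    d2 = (ox - target.x) ** 2 + (oy - target.y) ** 2
    cand = np.nonzero(d2 <= max_d2)[0]
    if cand.size == 0:
        return False
    for i in cand[np.argsort(d2[cand])]:
        if ocells[i] == (r, c):
            return True
        if _segment_clears(terrain, dem, ox[i], oy[i], oz[i], target.x, target.y, z1):
            return True
    return False


def viewshed(
    dem: ElevationGrid,
    observers: list[Observer],
    max_distance: float | None = None,
    target_height: float = 0.0,
) -> VisibilityGrid:
    """Union of single-observer visibility over all observers.

    A cell is visible iff :func:`line_of_sight` succeeds from at least one
    observer within ``max_distance`` (unlimited when None, the default: the
    study's viewsheds are reported per analysis square without a radius).
    Zero observers give an all-invisible grid; nodata cells are never
    visible.  Observers are tried nearest-first so cells near a road are
    resolved with a single short ray.
    """
    vis = np.zeros(dem.values.shape, dtype=bool)
    if observers:
        terrain = _opaque_terrain(dem)
        ox, oy, ocells, oz = _prepare_observers(dem, observers)
        max_d2 = np.inf if max_distance is None else float(max_distance) ** 2
        valid = dem.mask
        for r in range(dem.n_rows):
            for c in range(dem.n_cols):
                if not valid[r, c]:
                    continue
                target = dem.cell_center(r, c)
                vis[r, c] = _visible_from_any(terrain, dem, target, r, c,
                                              ox, oy, ocells, oz,
                                              target_height, max_d2)
    return dem.like(vis, nodata=None)


def visibility_at_points(
    dem: ElevationGrid,
    points: list[GridPoint],
    observers: list[Observer],
    max_distance: float | None = None,
    target_height: float = 0.0,
) -> list[bool]:
    """Per-point visibility (same semantics as :func:`viewshed`, sparse targets)."""
    if not observers:
        return [False] * len(points)
    terrain = _opaque_terrain(dem)
    ox, oy, ocells, oz = _prepare_observers(dem, observers)
    max_d2 = np.inf if max_distance is None else float(max_distance) ** 2
    out = []
    for p in points:
        r, c = dem.point_to_cell(p)
        if not dem.mask[r, c]:
            out.append(False)
            continue
        out.append(_visible_from_any(terrain, dem, p, r, c, ox, oy, ocells, oz,
                                     target_height, max_d2))
    return out


def visible_fraction(vis: VisibilityGrid, region_mask: np.ndarray) -> float:
    """Percentage of in-region cells that are visible."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != vis.values.shape:
        raise InvalidInputError("region mask and visibility grid shapes differ")
    n = int(region_mask.sum())
    if n == 0:
        raise UndefinedRatioError("empty region")
    return 100.0 * int((vis.values.astype(bool) & region_mask).sum()) / n
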