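"""Synthetic landscapes, road networks, nest sites, and observation processes.

The generator emulates the statistical structure the analysis assumes so the
whole pipeline runs with no external data:

* terrain: a smooth low-frequency base surface plus a set of finite linear
  *scarps* — ramps of configurable height over a narrow face — whose face
  cells are the ground-truth cliff class;
* roads: a jittered lattice of polylines, mostly paved with some unpaved
  tracks; a random subset of paved segments totalling ``coverage_fraction``
  of paved length is flagged imagery-covered (default 0.49).  Scarps are
  placed with a setback from covered roads — real roads skirt cliff faces —
  which spreads nest-to-road distances across the identification limit;
* nest sites: cells drawn from the cliff truth mask, with independent
  field-feature flags at configured prevalences (white spots 0.77, caves
  0.59, vegetation 0.76) and species occupancy shares;
* identification: a logistic distance-decay (midpoint ``d50``, scale ``s``)
  gated by visibility from covered roads, with per-feature remote-detection
  probabilities conditional on identification;
* survey times: per-square per-km^2 inspection rates drawn from lognormal
  distributions matched by moments to the configured mean/SD.

Every draw is fixed by ``SyntheticConfig.seed``; each operation derives an
independent substream, so results are reproducible regardless of call order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .cliff_classifier import CliffSite, LIMESTONE, NON_LIMESTONE
from .detectability import nearest_covered_road_distance
from .errors import InvalidInputError
from .roads import PAVED, UNPAVED, Road, RoadNetwork
from .survey_economics import SquareMetrics
from .terrain import ElevationGrid, GridPoint, RasterGrid

__all__ = [
    "SyntheticConfig",
    "make_landscape",
    "make_roads",
    "make_nest_sites",
    "simulate_identification",
    "simulate_survey_times",
]

# substream tags so each generator op draws independently from one seed
_STREAM_ROADS = 1
_STREAM_LANDSCAPE = 2
_STREAM_SITES = 3
_STREAM_IDENTIFY = 4
_STREAM_TIMES = 5


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic landscape.

    Defaults reflect the field system being emulated: ~49% of the paved
    network imagery-covered, feature prevalences of 0.77/0.59/0.76, a
    logistic identification limit around 1 km (d50 = 1000 m, scale 150 m),
    and per-km^2 inspection rates of 0.91 (remote) and 3.97 (ground)
    min km^-2.  Geometry defaults give an 8x8 km landscape at 50 m cells —
    large enough for nest-to-road distances to straddle the 1 km limit
    while keeping exact viewsheds affordable.
    """

    # grid geometry
    n_rows: int = 160
    n_cols: int = 160
    cell_size: float = 50.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    # base terrain
    base_amplitude: float = 40.0     # m
    base_wavelength: float = 1800.0  # m
    # scarps (cliff faces)
    n_scarps: int = 12
    scarp_height_min: float = 40.0   # m
    scarp_height_max: float = 120.0  # m
    scarp_face_cells: float = 2.0    # face width, in cells -> gradient h / (w * cs)
    scarp_length: float = 800.0      # m along strike
    scarp_road_setback: float = 500.0  # min distance of scarp centre to covered roads
    # roads
    road_spacing: float = 1600.0
    road_segment_length: float = 1000.0
    unpaved_fraction: float = 0.35   # share of lattice lines that are dirt tracks
    coverage_fraction: float = 0.49  # imagery-covered share of paved length
    # nest sites
    n_nest_sites: int = 148
    prevalence_white_spots: float = 0.77
    prevalence_caves: float = 0.59
    prevalence_vegetation: float = 0.76
    p_both_species: float = 0.095
    p_griffon_only: float = 0.297    # egyptian-only share is the remainder
    p_limestone: float = 0.85
    # identification model
    d50: float = 1000.0              # m, logistic midpoint
    logistic_scale: float = 150.0    # m
    p_remote_white_spots: float = 0.40
    p_remote_caves: float = 0.28
    p_remote_vegetation: float = 0.65
    # survey time rates (min km^-2) and their per-square SD
    remote_rate_mean: float = 0.91
    remote_rate_sd: float = 0.21
    ground_rate_mean: float = 3.97
    ground_rate_sd: float = 2.94
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coverage_fraction", "unpaved_fraction", "prevalence_white_spots",
                     "prevalence_caves", "prevalence_vegetation", "p_both_species",
                     "p_griffon_only", "p_limestone", "p_remote_white_spots",
                     "p_remote_caves", "p_remote_vegetation"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
        for name in ("cell_size", "base_wavelength", "road_spacing",
                     "road_segment_length", "d50", "logistic_scale", "scarp_length"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.p_both_species + self.p_griffon_only > 1:
            raise InvalidInputError("species occupancy shares exceed 1")

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# -- roads ------------------------------------------------------------------

def make_roads(cfg: SyntheticConfig, grid: RasterGrid | None = None) -> RoadNetwork:
    """Jittered road lattice with partial imagery coverage.

    Lattice lines at ``road_spacing`` in both directions, each split into
    polyline segments of ~``road_segment_length``; a share of whole lines
    is unpaved.  Paved segments are accumulated in random order until the
    covered length reaches ``coverage_fraction`` of the paved total, the
    last segment being split at the exact residual, so the measured covered
    share matches the target almost exactly.
    """
    rng = cfg._rng(_STREAM_ROADS)
    cs = cfg.cell_size
    margin = 1.5 * cs
    ox, oy = cfg.origin_x, cfg.origin_y
    w, h = cfg.width, cfg.height

    def lattice_positions(extent: float) -> np.ndarray:
        span = extent - 2 * margin
        k = max(1, int(span // cfg.road_spacing) + 1)
        offset = (extent - (k - 1) * cfg.road_spacing) / 2
        return offset + cfg.road_spacing * np.arange(k)

    vertex_step = 4 * cs
    jitter = 0.3 * cs
    lines: list[np.ndarray] = []
    for x in lattice_positions(w):
        ys = np.arange(margin, h - margin + 1e-9, vertex_step)
        xs = np.clip(x + rng.uniform(-jitter, jitter, ys.size), margin, w - margin)
        lines.append(np.column_stack([ox + xs, oy + ys]))
    for y in lattice_positions(h):
        xs = np.arange(margin, w - margin + 1e-9, vertex_step)
        ys = np.clip(y + rng.uniform(-jitter, jitter, xs.size), margin, h - margin)
        lines.append(np.column_stack([ox + xs, oy + ys]))

    roads: list[Road] = []
    paved_segments: list[int] = []
    for li, coords in enumerate(lines):
        surface = UNPAVED if rng.random() < cfg.unpaved_fraction else PAVED
        from shapely.geometry import LineString
        line = LineString(coords)
        n_seg = max(1, int(round(line.length / cfg.road_segment_length)))
        breaks = np.linspace(0, line.length, n_seg + 1)
        for si in range(n_seg):
            dists = np.linspace(breaks[si], breaks[si + 1], max(2, int((breaks[si + 1] - breaks[si]) / vertex_step) + 2))
            pts = np.array([[line.interpolate(d).x, line.interpolate(d).y] for d in dists])
            road = Road(road_id=f"road_{li:02d}_{si:02d}", coords=pts, surface=surface)
            if surface == PAVED:
                paved_segments.append(len(roads))
            roads.append(road)

    paved_total = sum(roads[i].length for i in paved_segments)
    target = cfg.coverage_fraction * paved_total
    order = rng.permutation(len(paved_segments))
    covered_len = 0.0
    for oi in order:
        idx = paved_segments[oi]
        road = roads[idx]
        remaining = target - covered_len
        if remaining <= 1e-9:
            break
        if road.length <= remaining + 1e-6:
            road.covered = True
            covered_len += road.length
        else:
            # split at the exact residual so coverage hits the target
            from shapely.geometry import LineString
            line = LineString(road.coords)
            k = max(2, int(remaining / vertex_step) + 2)
            part1 = np.array([[line.interpolate(d).x, line.interpolate(d).y]
                              for d in np.linspace(0, remaining, k)])
            k2 = max(2, int((line.length - remaining) / vertex_step) + 2)
            part2 = np.array([[line.interpolate(d).x, line.interpolate(d).y]
                              for d in np.linspace(remaining, line.length, k2)])
            roads[idx] = Road(road_id=road.road_id + "a", coords=part1,
                              surface=PAVED, covered=True)
            roads.append(Road(road_id=road.road_id + "b", coords=part2, surface=PAVED))
            covered_len += remaining
            break
    return RoadNetwork(roads)


# -- landscape --------------------------------------------------------------

def make_landscape(
    cfg: SyntheticConfig, roads: RoadNetwork | None = None
) -> tuple[ElevationGrid, np.ndarray]:
    """Base surface plus linear scarps; returns (DEM, cliff truth mask).

    The base is a smooth double-sinusoid of the configured amplitude and
    wavelength.  Each scarp is a finite ramp of random height rising over a
    face of ``scarp_face_cells`` cells across strike, tapered along strike.
    Truth-mask cells are those whose centre lies on a scarp face.  When a
    road network is given (or ``scarp_road_setback`` > 0, in which case the
    matching network is generated internally), scarp centres keep the
    configured setback from imagery-covered roads.
    """
    if cfg.n_scarps > 0 and roads is None and cfg.scarp_road_setback > 0:
        roads = make_roads(cfg)
    rng = cfg._rng(_STREAM_LANDSCAPE)
    cs = cfg.cell_size
    cols = np.arange(cfg.n_cols)
    rows = np.arange(cfg.n_rows)
    X = cfg.origin_x + (cols[None, :] + 0.5) * cs
    Y = cfg.origin_y + (cfg.n_rows - rows[:, None] - 0.5) * cs

    ph = rng.uniform(0, 2 * np.pi, size=4)
    k = 2 * np.pi / cfg.base_wavelength
    z = cfg.base_amplitude * (
        np.sin(k * X + ph[0]) * np.sin(k * Y + ph[1])
        + 0.4 * np.sin(0.5 * k * X + ph[2]) * np.sin(0.7 * k * Y + ph[3])
    )

    face_w = cfg.scarp_face_cells * cs
    max_height = cfg.scarp_height_max
    if max_height > 10 * cfg.base_amplitude + face_w * 100:
        raise InvalidInputError("scarp height not representable on this grid")

    covered_lines = [r.line for r in roads.select(covered_only=True)] if roads else []
    from shapely.geometry import Point

    truth = np.zeros((cfg.n_rows, cfg.n_cols), dtype=bool)
    margin = 3 * cs
    quad = 0
    for _ in range(cfg.n_scarps):
        # stratify centres over quadrants so every analysis square holds cliffs
        for _try in range(400):
            qx, qy = quad % 2, (quad // 2) % 2
            cx = cfg.origin_x + rng.uniform(margin + qx * cfg.width / 2,
                                            (qx + 1) * cfg.width / 2 - margin)
            cy = cfg.origin_y + rng.uniform(margin + qy * cfg.height / 2,
                                            (qy + 1) * cfg.height / 2 - margin)
            if not covered_lines or cfg.scarp_road_setback <= 0:
                break
            pt = Point(cx, cy)
            if min(ln.distance(pt) for ln in covered_lines) >= cfg.scarp_road_setback:
                break
        quad += 1
        theta = rng.uniform(0, np.pi)
        height = rng.uniform(cfg.scarp_height_min, cfg.scarp_height_max)
        nx, ny = np.cos(theta), np.sin(theta)       # across-strike normal
        tx, ty = -ny, nx                             # along-strike tangent
        s_perp = (X - cx) * nx + (Y - cy) * ny
        s_along = (X - cx) * tx + (Y - cy) * ty
        half_len = cfg.scarp_length / 2
        taper_w = 4 * cs
        ramp = np.clip(s_perp / face_w + 0.5, 0.0, 1.0)
        taper = np.clip((half_len + taper_w - np.abs(s_along)) / taper_w, 0.0, 1.0)
        z += height * ramp * taper
        truth |= (np.abs(s_perp) < face_w / 2) & (np.abs(s_along) <= half_len)

    grid = RasterGrid(values=z, cell_size=cs, origin_x=cfg.origin_x,
                      origin_y=cfg.origin_y, nodata=-9999.0)
    return grid, truth


# -- nest sites -------------------------------------------------------------

def make_nest_sites(
    truth_mask: np.ndarray, cfg: SyntheticConfig, grid: RasterGrid
) -> list[CliffSite]:
    """Nest sites drawn without replacement from the cliff truth mask."""
    rng = cfg._rng(_STREAM_SITES)
    truth = np.asarray(truth_mask, dtype=bool)
    # keep nests off the outermost ring, where the slope surface is undefined
    interior = np.zeros_like(truth)
    interior[1:-1, 1:-1] = True
    cells = np.flatnonzero(truth & interior)
    if cells.size < cfg.n_nest_sites:
        raise InvalidInputError(
            f"truth mask has {cells.size} cliff cells, need {cfg.n_nest_sites} sites"
        )
    chosen = rng.choice(cells, size=cfg.n_nest_sites, replace=False)
    p_eg_only = 1.0 - cfg.p_both_species - cfg.p_griffon_only
    occ = rng.choice(3, size=cfg.n_nest_sites,
                     p=[cfg.p_griffon_only, p_eg_only, cfg.p_both_species])
    sites = []
    for i, flat in enumerate(chosen):
        r, c = np.unravel_index(flat, np.asarray(truth_mask).shape)
        sites.append(CliffSite(
            id=f"site_{i:04d}",
            position=grid.cell_center(int(r), int(c)),
            occupied_by_griffon=occ[i] in (0, 2),
            occupied_by_egyptian=occ[i] in (1, 2),
            has_white_spots=bool(rng.random() < cfg.prevalence_white_spots),
            has_cave=bool(rng.random() < cfg.prevalence_caves),
            has_vegetation=bool(rng.random() < cfg.prevalence_vegetation),
            substrate=LIMESTONE if rng.random() < cfg.p_limestone else NON_LIMESTONE,
        ))
    return sites


# -- observation processes --------------------------------------------------

def simulate_identification(
    sites: list[CliffSite],
    roads: RoadNetwork,
    vis: RasterGrid | None,
    cfg: SyntheticConfig,
    site_visibility: list[bool] | None = None,
) -> tuple[list[CliffSite], np.ndarray]:
    """Set remote flags on a copy of ``sites``; returns (sites, distances).

    A site is identified with probability logistic((d50 - d) / s) where d is
    its distance to the nearest covered road, gated by visibility: an
    invisible site is never identified.  Visibility comes from ``vis`` (a
    viewshed grid), or ``site_visibility`` (per-site booleans), or is
    assumed true when both are None.  Remote feature flags thin the field
    flags with the per-feature detection probabilities, independently across
    features, conditional on identification.
    """
    rng = cfg._rng(_STREAM_IDENTIFY)
    dists = np.array([nearest_covered_road_distance(s.position, roads) for s in sites])
    p_ident = expit((cfg.d50 - dists) / cfg.logistic_scale)
    out = []
    for i, site in enumerate(sites):
        if site_visibility is not None:
            visible = bool(site_visibility[i])
        elif vis is not None:
            r, c = vis.point_to_cell(site.position)
            visible = bool(vis.values[r, c])
        else:
            visible = True
        identified = visible and (rng.random() < p_ident[i])
        out.append(dataclasses.replace(
            site,
            remote_identified=identified,
            remote_white_spots=identified and site.has_white_spots
                and (rng.random() < cfg.p_remote_white_spots),
            remote_cave=identified and site.has_cave
                and (rng.random() < cfg.p_remote_caves),
            remote_vegetation=identified and site.has_vegetation
                and (rng.random() < cfg.p_remote_vegetation),
        ))
    return out, dists


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean and SD."""
    var = sd**2
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def simulate_survey_times(
    squares: list[SquareMetrics], cfg: SyntheticConfig,
    fill: tuple[str, ...] = ("remote", "ground"),
) -> list[SquareMetrics]:
    """Fill per-square survey times from lognormal per-km^2 rates.

    Rates are strictly positive; with SD 0 the draw degenerates to the mean
    and times are exactly rate x viewshed area.
    """
    rng = cfg._rng(_STREAM_TIMES)
    out = []
    for sq in squares:
        sq = dataclasses.replace(sq)
        if "remote" in fill:
            if cfg.remote_rate_sd > 0:
                mu, sig = _lognormal_params(cfg.remote_rate_mean, cfg.remote_rate_sd)
                rate = rng.lognormal(mu, sig)
            else:
                rate = cfg.remote_rate_mean
            sq.time_remote_min = rate * sq.viewshed_remote_km2
        if "ground" in fill:
            if cfg.ground_rate_sd > 0:
                mu, sig = _lognormal_params(cfg.ground_rate_mean, cfg.ground_rate_sd)
                rate = rng.lognormal(mu, sig)
            else:
                rate = cfg.ground_rate_mean
            sq.time_ground_min = rate * sq.viewshed_ground_km2
        out.append(sq)
    return out
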