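"""End-to-end orchestration: synthesis -> viewsheds -> maps -> reports.

``run_full_analysis`` sequences the whole procedure on a synthetic
landscape: terrain and slope, remote and on-ground viewsheds from road
observers, occupied-slope thresholds and the three cliff maps, stratified
ground-truth sampling and the accuracy table, per-square survey economics,
and the detectability / feature-detection analysis.  Outputs are plain CSV
and ESRI ASCII files plus a manifest recording the seed, a config hash and
a content hash, so a run is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from . import accuracy as acc
from .cliff_classifier import CliffMap, classify, occupied_slope_sample, thresholds_from_sample, write_sites_csv
from .detectability import (
    distance_summary,
    feature_detection_table,
    identification_summary,
    welch_t_from_samples,
)
from .errors import CliffscoutError
from .roads import RoadNetwork, write_roads_geojson
from .survey_economics import (
    CostParams,
    SquareMetrics,
    combined_savings,
    ground_cost,
    ground_time,
    paired_t,
    per_area_rate,
    wilcoxon_signed_rank,
)
from .synthetic_data import (
    SyntheticConfig,
    make_landscape,
    make_nest_sites,
    make_roads,
    simulate_identification,
    simulate_survey_times,
)
from .terrain import RasterGrid, slope, write_esri_ascii
from .viewshed import observers_along_roads, viewshed, visible_fraction

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_full_analysis", "render_reports", "PipelineResult"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {},  # overrides for SyntheticConfig fields
    "viewshed": {
        "eye_height": 2.5,
        "observer_spacing": 100.0,   # m along roads; 2 cells at the default grid
        "max_distance": 3500.0,      # m; caps ray length at desk scale
    },
    "economics": {
        "ground_speed_kmh": 30.0,
        "euro_per_km": 0.19,
    },
    "accuracy": {
        "n_cliff": 50,
        "n_noncliff": 50,
    },
    "squares": {"n_side": 2},
    "outputs": {"write_rasters": True},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source: str | Path | dict | None = None) -> dict:
    """Resolve a config (YAML/JSON file or dict) against the embedded defaults."""
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        text = Path(source).read_text()
        user = yaml.safe_load(text) or {}
    return _deep_merge(DEFAULT_CONFIG, user)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=float).encode()).hexdigest()


def _square_masks(grid: RasterGrid, n_side: int) -> list[np.ndarray]:
    """Partition the grid into n_side x n_side survey squares (by cell index)."""
    masks = []
    row_edges = np.linspace(0, grid.n_rows, n_side + 1).astype(int)
    col_edges = np.linspace(0, grid.n_cols, n_side + 1).astype(int)
    for i in range(n_side):
        for j in range(n_side):
            m = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
            m[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = True
            masks.append(m)
    return masks


def _square_bbox(grid: RasterGrid, mask: np.ndarray):
    rows, cols = np.nonzero(mask)
    cs = grid.cell_size
    x0 = grid.origin_x + cols.min() * cs
    x1 = grid.origin_x + (cols.max() + 1) * cs
    y1 = grid.y_top - rows.min() * cs
    y0 = grid.y_top - (rows.max() + 1) * cs
    return box(x0, y0, x1, y1)


def _road_km_in(roads: RoadNetwork, geom, covered_only: bool = False) -> float:
    total = 0.0
    for r in roads.select(covered_only=covered_only):
        total += r.line.intersection(geom).length
    return total / 1000.0


@dataclass
class PipelineResult:
    config: dict
    seed: int
    dem: RasterGrid
    truth_mask: np.ndarray
    slopes: RasterGrid
    roads: RoadNetwork
    vis_remote: RasterGrid
    vis_ground: RasterGrid
    thresholds: object
    maps: dict
    points: list
    sites: list
    site_distances: np.ndarray
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    savings: dict
    stats: dict
    manifest: dict = field(default_factory=dict)


def _stage(name: str, t0: float, manifest: dict) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-16s %6.2f s", name, t1 - t0)
    manifest.setdefault("stages", []).append({"name": name, "seconds": round(t1 - t0, 3)})
    return t1


def run_full_analysis(
    config: str | Path | dict | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full synthetic analysis; optionally write the report bundle."""
    cfgd = load_config(config)
    if seed is not None:
        cfgd["seed"] = int(seed)
    run_seed = int(cfgd["seed"])
    syn = SyntheticConfig(**cfgd["synthetic"], seed=run_seed)
    vcfg = cfgd["viewshed"]
    params = CostParams(ground_speed_kmh=cfgd["economics"]["ground_speed_kmh"],
                        euro_per_km=cfgd["economics"]["euro_per_km"])
    manifest: dict = {"seed": run_seed, "config_hash": _config_hash(cfgd)}
    t0 = time.perf_counter()

    # terrain and roads
    roads = make_roads(syn)
    dem, truth = make_landscape(syn, roads=roads)
    slopes = slope(dem)
    t0 = _stage("terrain", t0, manifest)

    # viewsheds from road observers
    spacing = vcfg["observer_spacing"]
    obs_remote = observers_along_roads(roads, spacing, covered_only=True,
                                       eye_height=vcfg["eye_height"])
    obs_ground = observers_along_roads(roads, spacing, covered_only=False,
                                       eye_height=vcfg["eye_height"])
    vis_remote = viewshed(dem, obs_remote, max_distance=vcfg["max_distance"])
    vis_ground = viewshed(dem, obs_ground, max_distance=vcfg["max_distance"])
    t0 = _stage("viewshed", t0, manifest)

    # occupied-slope thresholds and cliff maps
    sites = make_nest_sites(truth, syn, dem)
    sample = occupied_slope_sample(slopes, sites)
    thresholds = thresholds_from_sample(sample)
    maps = {
        "smin": classify(slopes, thresholds.s_min),
        "s25": classify(slopes, thresholds.s_25),
        "s50": classify(slopes, thresholds.s_50),
    }
    t0 = _stage("classify", t0, manifest)

    # ground-truth sampling within the remotely surveyed area
    squares = _square_masks(dem, cfgd["squares"]["n_side"])
    region = vis_remote.values.astype(bool) & slopes.mask
    points = sample_points = acc.sample_ground_truth(
        dem, region, truth,
        n_cliff=cfgd["accuracy"]["n_cliff"],
        n_noncliff=cfgd["accuracy"]["n_noncliff"],
        strata=squares,
        seed=np.random.SeedSequence([run_seed, 7]).generate_state(1)[0] % (2**31),
    )
    # street-view analogue: within the surveyed area, imagery shows the true class
    sv_map = CliffMap(grid=dem.like(truth.copy(), nodata=None),
                      valid=np.ones_like(truth, dtype=bool), threshold=float("nan"))
    methods = {"street_view": sv_map, **maps}
    table2 = _accuracy_table(methods, points)
    t0 = _stage("accuracy", t0, manifest)

    # survey economics per square
    cell_km2 = (dem.cell_size / 1000.0) ** 2
    sq_metrics: list[SquareMetrics] = []
    for i, m in enumerate(squares):
        geom = _square_bbox(dem, m)
        road_km = _road_km_in(roads, geom)
        sq = SquareMetrics(
            square_id=f"sq_{i}",
            area_km2=float(m.sum()) * cell_km2,
            road_km_ground=road_km,
            viewshed_ground_km2=float((vis_ground.values.astype(bool) & m).sum()) * cell_km2,
            viewshed_remote_km2=float((vis_remote.values.astype(bool) & m).sum()) * cell_km2,
        )
        sq.time_ground_min = ground_time(road_km, params)
        sq_metrics.append(sq)
    sq_metrics = simulate_survey_times(sq_metrics, syn, fill=("remote",))
    per_sq_savings = [combined_savings(sq, params) for sq in sq_metrics]
    savings = {
        "pct_time_mean": float(np.mean([s["pct_time"] for s in per_sq_savings])),
        "pct_cost_mean": float(np.mean([s["pct_cost"] for s in per_sq_savings])),
        "time_saved_min_mean": float(np.mean([s["time_saved_min"] for s in per_sq_savings])),
        "cost_saved_eur_mean": float(np.mean([s["cost_saved_eur"] for s in per_sq_savings])),
    }
    rate_remote = [per_area_rate(sq.time_remote_min, sq.viewshed_remote_km2) for sq in sq_metrics]
    rate_ground = [per_area_rate(sq.time_ground_min, sq.viewshed_ground_km2) for sq in sq_metrics]
    pct_remote = [visible_fraction(vis_remote, m) for m in squares]
    pct_ground = [visible_fraction(vis_ground, m) for m in squares]
    try:
        t_viewshed = paired_t(pct_remote, pct_ground)
    except CliffscoutError:  # identical coverages leave nothing to compare
        t_viewshed = None
    stats = {
        "wilcoxon_time_rates": wilcoxon_signed_rank(rate_remote, rate_ground),
        "paired_t_viewshed_pct": t_viewshed,
        "viewshed_remote_pct_mean": float(np.mean(pct_remote)),
        "viewshed_ground_pct_mean": float(np.mean(pct_ground)),
    }
    table1 = _economics_table(sq_metrics, per_sq_savings, params)
    t0 = _stage("economics", t0, manifest)

    # detectability of nesting cliffs from covered roads
    id_sites, dists = simulate_identification(sites, roads, vis_remote, syn)
    ident = np.array([s.remote_identified for s in id_sites])
    stats["n_sites"] = len(id_sites)
    stats["identified_pct"] = 100.0 * ident.mean()
    if 2 <= ident.sum() <= len(ident) - 2:
        w = welch_t_from_samples(dists[~ident], dists[ident])
        stats["welch_t_distance"] = w.t
        stats["welch_p_distance"] = w.p
    if ident.any():
        stats["identified_distance"] = distance_summary(dists[ident])
    table3 = _table3(id_sites)
    t0 = _stage("detectability", t0, manifest)

    result = PipelineResult(
        config=cfgd, seed=run_seed, dem=dem, truth_mask=truth, slopes=slopes,
        roads=roads, vis_remote=vis_remote, vis_ground=vis_ground,
        thresholds=thresholds, maps=maps, points=points, sites=id_sites,
        site_distances=dists, table1=table1, table2=table2, table3=table3,
        savings=savings, stats=stats, manifest=manifest,
    )
    manifest["version"] = _package_version()
    manifest["content_hash"] = _content_hash(result)
    if out_dir is not None:
        render_reports(result, out_dir)
    return result


def _accuracy_table(methods: dict, points) -> pd.DataFrame:
    rows: dict[str, dict] = {}
    for name, cliff_map in methods.items():
        cm = acc.evaluate(cliff_map, points)
        rows[name] = {
            "cliffs_correct": cm.tp, "cliffs_incorrect": cm.fn,
            "noncliff_correct": cm.tn, "noncliff_incorrect": cm.fp,
            "overall_accuracy_pct": round(acc.overall_accuracy(cm)),
            "producers_accuracy_pct": round(acc.producers_accuracy(cm)),
            "users_accuracy_pct": round(acc.users_accuracy(cm)),
            "omission_error_rate": round(acc.omission_error_rate(cm), 2),
            "commission_error_rate": round(acc.commission_error_rate(cm), 2),
            "cohens_kappa": round(acc.cohens_kappa(cm), 2),
        }
    return pd.DataFrame(rows)


def _economics_table(sq_metrics, per_sq_savings, params: CostParams) -> pd.DataFrame:
    rows = []
    for sq, sv in zip(sq_metrics, per_sq_savings):
        rows.append({
            "square_id": sq.square_id,
            "area_km2": round(sq.area_km2, 2),
            "road_km_ground": round(sq.road_km_ground, 2),
            "viewshed_ground_pct": round(100 * sq.viewshed_ground_km2 / sq.area_km2, 1),
            "viewshed_remote_pct": round(100 * sq.viewshed_remote_km2 / sq.area_km2, 1),
            "time_ground_min_km2": round(per_area_rate(sq.time_ground_min, sq.viewshed_ground_km2), 2),
            "time_remote_min_km2": round(per_area_rate(sq.time_remote_min, sq.viewshed_remote_km2), 2)
                if sq.viewshed_remote_km2 > 0 else float("nan"),
            "cost_ground_eur_km2": round(per_area_rate(
                ground_cost(sq.road_km_ground, params), sq.viewshed_ground_km2), 2),
            "cost_remote_eur_km2": 0.00,
            "time_saved_min": round(sv["time_saved_min"], 1),
            "cost_saved_eur": round(sv["cost_saved_eur"], 2),
            "pct_time_saved": round(sv["pct_time"], 1),
            "pct_cost_saved": round(sv["pct_cost"], 1),
        })
    return pd.DataFrame(rows).set_index("square_id")


def _table3(sites) -> pd.DataFrame:
    ident = identification_summary(sites)
    feat = feature_detection_table(sites)
    feat = feat.rename(columns={"field_n": "n_cliffs", "remote_n": "identified",
                                "remote_pct": "identified_pct"})
    return pd.concat([ident, feat[["n_cliffs", "identified", "identified_pct"]]])


def _package_version() -> str:
    from . import __version__
    return __version__


def _content_hash(result: PipelineResult) -> str:
    h = hashlib.sha256()
    for df in (result.table1, result.table2, result.table3):
        h.update(df.to_csv().encode())
    h.update(np.ascontiguousarray(result.dem.values).tobytes())
    h.update(np.packbits(result.vis_remote.values.astype(bool)).tobytes())
    h.update(json.dumps(result.savings, sort_keys=True).encode())
    return h.hexdigest()


def render_reports(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write the report bundle (CSV tables, rasters, vectors, manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (("table1_economics.csv", result.table1),
                     ("table2_accuracy.csv", result.table2),
                     ("table3_detection.csv", result.table3)):
        p = out / name
        df.to_csv(p)
        paths.append(p)
    write_sites_csv(result.sites, out / "sites.csv")
    write_roads_geojson(result.roads, out / "roads.geojson")
    if result.config.get("outputs", {}).get("write_rasters", True):
        write_esri_ascii(result.dem, out / "dem.asc")
        write_esri_ascii(result.slopes, out / "slope.asc")
        write_esri_ascii(result.vis_remote, out / "visibility_remote.asc")
        write_esri_ascii(result.vis_ground, out / "visibility_ground.asc")
        for name, m in result.maps.items():
            write_esri_ascii(m.grid, out / f"cliffs_{name}.asc")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    paths.append(out / "manifest.json")
    return paths
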