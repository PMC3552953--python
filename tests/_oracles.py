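"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the dense-ray
visibility oracle samples bilinear terrain at a fine step instead of using
grid-line crossings, and the signed-rank oracle enumerates the exact null.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.ndimage import gaussian_filter

from cliffscout.terrain import RasterGrid


def smooth_random_dem(seed: int, n: int = 20, cell_size: float = 10.0,
                      amplitude: float = 20.0, sigma: float = 2.0) -> RasterGrid:
    """Rugged but spatially correlated random terrain."""
    rng = np.random.default_rng(seed)
    z = gaussian_filter(rng.normal(size=(n, n)), sigma=sigma)
    z *= amplitude / max(z.std(), 1e-12)
    return RasterGrid(values=z, cell_size=cell_size, nodata=None)


def bilinear(dem: RasterGrid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of terrain between cell centres (edge-clamped)."""
    cs = dem.cell_size
    cf = np.clip((x - dem.origin_x) / cs - 0.5, 0, dem.n_cols - 1)
    rf = np.clip((dem.y_top - y) / cs - 0.5, 0, dem.n_rows - 1)
    c0 = np.floor(cf).astype(int)
    r0 = np.floor(rf).astype(int)
    c1 = np.minimum(c0 + 1, dem.n_cols - 1)
    r1 = np.minimum(r0 + 1, dem.n_rows - 1)
    fc = cf - c0
    fr = rf - r0
    v = dem.values
    return ((v[r0, c0] * (1 - fc) + v[r0, c1] * fc) * (1 - fr)
            + (v[r1, c0] * (1 - fc) + v[r1, c1] * fc) * fr)


def dense_ray_visible(dem: RasterGrid, obs_xy, eye_height: float,
                      target_xy, target_height: float = 0.0,
                      step_frac: float = 0.1) -> bool:
    """Visibility by dense sampling (every cell_size * step_frac) of bilinear terrain."""
    x0, y0 = obs_xy
    x1, y1 = target_xy
    from cliffscout.terrain import GridPoint
    r0, c0 = dem.point_to_cell(GridPoint(x0, y0))
    r1, c1 = dem.point_to_cell(GridPoint(x1, y1))
    if (r0, c0) == (r1, c1):
        return True
    z0 = dem.values[r0, c0] + eye_height
    z1 = dem.values[r1, c1] + target_height
    dist = float(np.hypot(x1 - x0, y1 - y0))
    n = max(int(np.ceil(dist / (dem.cell_size * step_frac))), 2)
    t = np.linspace(0.0, 1.0, n + 1)[1:-1]
    terr = bilinear(dem, x0 + t * (x1 - x0), y0 + t * (y1 - y0))
    sight = z0 + t * (z1 - z0)
    eps = 1e-9 * (1.0 + abs(z0) + abs(z1))
    return not np.any(terr > sight + eps)


def exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns.

    Requires no zeros and no tied |d|.  Returns (V, p) with V the sum of
    positive ranks and p = min(1, 2 * min(P(W <= V), P(W >= V))).
    """
    d = np.asarray(d, dtype=float)
    assert np.all(d != 0) and len(set(np.abs(d))) == len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    v = float(ranks[d > 0].sum())
    n = len(d)
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([0, 1], repeat=n)]
    ws = np.array(ws, dtype=float)
    p = min(1.0, 2 * min(np.mean(ws <= v), np.mean(ws >= v)))
    return v, p
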