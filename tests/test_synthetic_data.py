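"""Synthetic landscape, road, site, and observation-process generators."""

import numpy as np
import pytest

from cliffscout.cliff_classifier import CliffSite
from cliffscout.roads import Road, RoadNetwork
from cliffscout.survey_economics import SquareMetrics
from cliffscout.synthetic_data import (
    SyntheticConfig,
    make_landscape,
    make_nest_sites,
    make_roads,
    simulate_identification,
    simulate_survey_times,
)
from cliffscout.terrain import GridPoint, RasterGrid, slope


def small_cfg(**kw):
    defaults = dict(n_rows=60, n_cols=60, cell_size=50.0, n_scarps=4,
                    scarp_length=600.0, scarp_road_setback=0.0,
                    road_spacing=800.0, n_nest_sites=20, seed=0)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestLandscape:
    def test_deterministic_given_seed(self):
        cfg = small_cfg(seed=42)
        d1, t1 = make_landscape(cfg)
        d2, t2 = make_landscape(cfg)
        np.testing.assert_array_equal(d1.values, d2.values)
        np.testing.assert_array_equal(t1, t2)

    def test_zero_scarps_gentle_terrain(self):
        cfg = small_cfg(n_scarps=0, base_amplitude=10.0, base_wavelength=3000.0)
        dem, truth = make_landscape(cfg)
        assert not truth.any()
        s = slope(dem)
        assert s.values[s.mask].max() < 0.1

    def test_scarp_face_gradient_recovered_by_slope(self):
        # one effectively infinite scarp: height 40 m over a 4-cell (20 m) face
        # is a gradient of 2.0, which the slope operator recovers exactly on
        # face cells whose 3x3 window lies entirely within the ramp
        cfg = SyntheticConfig(n_rows=40, n_cols=40, cell_size=5.0, base_amplitude=0.0,
                              n_scarps=1, scarp_height_min=40.0, scarp_height_max=40.0,
                              scarp_face_cells=4.0, scarp_length=1e6,
                              scarp_road_setback=0.0, seed=3)
        dem, truth = make_landscape(cfg)
        s = slope(dem)
        face = truth & s.mask
        assert face.any()
        assert s.values[face].max() == pytest.approx(2.0, rel=1e-9)

    def test_truth_cells_are_steep(self):
        cfg = small_cfg(seed=5)
        dem, truth = make_landscape(cfg)
        s = slope(dem)
        face = truth & s.mask
        # scarp faces are much steeper than the base surface on average
        assert s.values[face].mean() > 3 * s.values[s.mask & ~truth].mean()


class TestRoads:
    def test_coverage_zero_and_one(self):
        assert not any(r.covered for r in make_roads(small_cfg(coverage_fraction=0.0)).roads)
        net = make_roads(small_cfg(coverage_fraction=1.0))
        assert all(r.covered for r in net.select(surface="paved"))

    def test_covered_share_matches_target(self):
        for seed in range(5):
            net = make_roads(SyntheticConfig(seed=seed))
            assert net.covered_fraction() == pytest.approx(0.49, abs=0.02)

    def test_deterministic(self):
        a = make_roads(small_cfg(seed=9))
        b = make_roads(small_cfg(seed=9))
        assert len(a.roads) == len(b.roads)
        for ra, rb in zip(a.roads, b.roads):
            np.testing.assert_array_equal(ra.coords, rb.coords)
            assert (ra.surface, ra.covered) == (rb.surface, rb.covered)

    def test_roads_inside_grid_extent(self):
        cfg = small_cfg(seed=2)
        grid = RasterGrid(np.zeros((cfg.n_rows, cfg.n_cols)), cfg.cell_size, nodata=None)
        for r in make_roads(cfg).roads:
            for x, y in r.coords:
                assert grid.contains(GridPoint(x, y))


class TestNestSites:
    def grid(self, shape=(80, 80)):
        return RasterGrid(np.zeros(shape), 50.0, nodata=None)

    def test_sites_on_truth_cells(self):
        cfg = small_cfg(seed=1)
        dem, truth = make_landscape(cfg)
        for s in make_nest_sites(truth, cfg, dem):
            assert truth[dem.point_to_cell(s.position)]

    def test_prevalence_one_flags_everyone(self):
        cfg = small_cfg(n_nest_sites=50, prevalence_white_spots=1.0)
        truth = np.ones((80, 80), bool)
        sites = make_nest_sites(truth, cfg, self.grid())
        assert all(s.has_white_spots for s in sites)

    def test_prevalences_within_binomial_bounds(self):
        cfg = SyntheticConfig(n_nest_sites=5000, seed=12)
        truth = np.ones((80, 80), bool)
        sites = make_nest_sites(truth, cfg, self.grid())
        for attr, p in [("has_white_spots", 0.77), ("has_cave", 0.59),
                        ("has_vegetation", 0.76)]:
            obs = np.mean([getattr(s, attr) for s in sites])
            assert abs(obs - p) < 1.96 * np.sqrt(p * (1 - p) / 5000) * 1.5

    def test_every_site_occupied(self):
        cfg = small_cfg(seed=4)
        dem, truth = make_landscape(cfg)
        for s in make_nest_sites(truth, cfg, dem):
            assert s.occupied_by_griffon or s.occupied_by_egyptian

    def test_too_few_truth_cells_raises(self):
        cfg = small_cfg(n_nest_sites=50)
        truth = np.zeros((80, 80), bool)
        truth[0, :10] = True
        from cliffscout.errors import InvalidInputError
        with pytest.raises(InvalidInputError):
            make_nest_sites(truth, cfg, self.grid())


def straight_covered_road(height=20000.0):
    return RoadNetwork([Road("r", np.array([[0.0, 0.0], [0.0, height]]), covered=True)])


def sites_at_distances(dists, rng):
    return [CliffSite(id=f"s{i:05d}", position=GridPoint(float(d), float(rng.uniform(10, 19000))),
                      occupied_by_griffon=True, has_cave=bool(rng.random() < 0.6))
            for i, d in enumerate(dists)]


class TestIdentification:
    def test_midpoint_probability_half(self):
        cfg = SyntheticConfig(seed=21)
        rng = np.random.default_rng(0)
        sites = sites_at_distances(np.full(2000, cfg.d50), rng)
        out, dists = simulate_identification(sites, straight_covered_road(), None, cfg)
        np.testing.assert_allclose(dists, cfg.d50)
        frac = np.mean([s.remote_identified for s in out])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_invisible_never_identified(self):
        cfg = SyntheticConfig(seed=22)
        rng = np.random.default_rng(1)
        sites = sites_at_distances(np.zeros(200), rng)  # d = 0: p ~ 1 if visible
        out, _ = simulate_identification(sites, straight_covered_road(), None, cfg,
                                         site_visibility=[False] * 200)
        assert not any(s.remote_identified for s in out)

    def test_identified_nearer_than_unidentified(self):
        cfg = SyntheticConfig(seed=23)
        rng = np.random.default_rng(2)
        dists = rng.uniform(0, 2500, 2000)
        out, d = simulate_identification(sites_at_distances(dists, rng),
                                         straight_covered_road(), None, cfg)
        ident = np.array([s.remote_identified for s in out])
        assert 0 < ident.sum() < len(ident)
        assert np.median(d[ident]) < np.median(d[~ident])

    def test_remote_features_require_field_flag_and_identification(self):
        cfg = SyntheticConfig(seed=24, p_remote_caves=1.0)
        rng = np.random.default_rng(3)
        out, _ = simulate_identification(sites_at_distances(np.zeros(300), rng),
                                         straight_covered_road(), None, cfg)
        for s in out:
            if s.remote_cave:
                assert s.has_cave and s.remote_identified

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(seed=25)
        rng = np.random.default_rng(4)
        sites = sites_at_distances(rng.uniform(0, 2500, 100), rng)
        a, _ = simulate_identification(sites, straight_covered_road(), None, cfg)
        b, _ = simulate_identification(sites, straight_covered_road(), None, cfg)
        assert [s.remote_identified for s in a] == [s.remote_identified for s in b]


class TestSurveyTimes:
    def sq(self, i=0):
        return SquareMetrics(f"sq{i}", 100.0, 50.0, 97.4, 48.1)

    def test_zero_noise_exact(self):
        cfg = SyntheticConfig(remote_rate_sd=0.0, ground_rate_sd=0.0, seed=1)
        out = simulate_survey_times([self.sq()], cfg)
        assert out[0].time_remote_min == pytest.approx(0.91 * 48.1)
        assert out[0].time_ground_min == pytest.approx(3.97 * 97.4)

    def test_rates_nonnegative_and_mean_recovered(self):
        cfg = SyntheticConfig(seed=2)
        squares = [self.sq(i) for i in range(1000)]
        out = simulate_survey_times(squares, cfg)
        rates = np.array([sq.time_remote_min / sq.viewshed_remote_km2 for sq in out])
        assert (rates > 0).all()
        assert abs(rates.mean() - 0.91) < 3 * 0.21 / np.sqrt(1000)
        g_rates = np.array([sq.time_ground_min / sq.viewshed_ground_km2 for sq in out])
        assert abs(g_rates.mean() - 3.97) < 3 * 2.94 / np.sqrt(1000)
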