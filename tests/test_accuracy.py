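"""Confusion-matrix metrics and stratified ground-truth sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cliffscout.accuracy import (
    CLIFF,
    NON_CLIFF,
    ConfusionMatrix2x2,
    GroundTruthPoint,
    cohens_kappa,
    commission_error_rate,
    evaluate,
    omission_error_rate,
    overall_accuracy,
    producers_accuracy,
    sample_ground_truth,
    users_accuracy,
)
from cliffscout.errors import InfeasibleSamplingError, UndefinedRatioError
from cliffscout.terrain import RasterGrid


# Published accuracy-assessment columns for a 50/50 cliff / non-cliff
# ground-truth sample: street-level imagery and three DEM threshold maps.
PUBLISHED_COLUMNS = {
    # name: (tp, fn, fp, tn, overall, producers, users, omission, commission)
    "street_view": (50, 0, 0, 50, 100, 100, 100, 0.0, 0.0),
    "smin": (49, 1, 5, 45, 94, 98, 90, 0.02, 0.10),
    "s25": (29, 21, 0, 50, 79, 58, 100, 0.42, 0.0),
    "s50": (22, 28, 0, 50, 72, 44, 100, 0.56, 0.0),
}


class TestPublishedMetrics:
    @pytest.mark.parametrize("name", PUBLISHED_COLUMNS)
    def test_reference_relative_metrics(self, name):
        tp, fn, fp, tn, overall, prod, users, omis, comm = PUBLISHED_COLUMNS[name]
        cm = ConfusionMatrix2x2(tp, fn, fp, tn)
        assert overall_accuracy(cm) == pytest.approx(overall)
        assert producers_accuracy(cm) == pytest.approx(prod)
        assert users_accuracy(cm, convention="reference") == pytest.approx(users)
        assert omission_error_rate(cm) == pytest.approx(omis)
        assert commission_error_rate(cm, convention="reference") == pytest.approx(comm)

    def test_map_relative_convention_differs_for_smin(self):
        cm = ConfusionMatrix2x2(49, 1, 5, 45)
        assert users_accuracy(cm, convention="map") == pytest.approx(100 * 49 / 54)
        assert commission_error_rate(cm, convention="map") == pytest.approx(5 / 54)

    def test_perfect_matrix(self):
        cm = ConfusionMatrix2x2(50, 0, 0, 50)
        assert overall_accuracy(cm) == 100
        assert cohens_kappa(cm) == 1.0
        assert omission_error_rate(cm) == 0

    def test_kappa_closed_form_from_counts(self):
        # balanced reference classes make pe exactly 1/2, so kappa = 2*po - 1
        assert cohens_kappa(ConfusionMatrix2x2(49, 1, 5, 45)) == pytest.approx(0.88)
        assert cohens_kappa(ConfusionMatrix2x2(29, 21, 0, 50)) == pytest.approx(0.58)
        assert cohens_kappa(ConfusionMatrix2x2(22, 28, 0, 50)) == pytest.approx(0.44)

    def test_kappa_chance_agreement_zero(self):
        assert cohens_kappa(ConfusionMatrix2x2(25, 25, 25, 25)) == pytest.approx(0.0)

    def test_producers_symmetry_at_half(self):
        assert producers_accuracy(ConfusionMatrix2x2(13, 13, 4, 20)) == pytest.approx(50)


class TestMetricProperties:
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(1, 5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_kappa_balanced_closed_form(self, tp, fp, scale):
        n_ref = 60
        cm = ConfusionMatrix2x2(tp, n_ref - tp, fp, n_ref - fp)
        po = (cm.tp + cm.tn) / cm.n
        assert cohens_kappa(cm) == pytest.approx(2 * po - 1)
        # all metrics invariant under scaling the counts
        cm2 = ConfusionMatrix2x2(tp * scale, (n_ref - tp) * scale,
                                 fp * scale, (n_ref - fp) * scale)
        assert overall_accuracy(cm2) == pytest.approx(overall_accuracy(cm))
        assert cohens_kappa(cm2) == pytest.approx(cohens_kappa(cm))
        assert omission_error_rate(cm2) == pytest.approx(omission_error_rate(cm))

    @given(st.integers(1, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_overall_is_weighted_producer_mean(self, tp, fn, fp, tn):
        cm = ConfusionMatrix2x2(tp, fn, fp, tn)
        w_cliff = (tp + fn) / cm.n
        w_non = (fp + tn) / cm.n
        expect = w_cliff * producers_accuracy(cm, CLIFF) + w_non * producers_accuracy(cm, NON_CLIFF)
        assert overall_accuracy(cm) == pytest.approx(expect)

    def test_empty_matrix_raises(self):
        with pytest.raises(UndefinedRatioError):
            overall_accuracy(ConfusionMatrix2x2(0, 0, 0, 0))


class TestEvaluate:
    def grid(self, values):
        return RasterGrid(values=np.asarray(values, dtype=bool), cell_size=10.0, nodata=None)

    def points_from(self, grid, truth):
        pts = []
        for r in range(truth.shape[0]):
            for c in range(truth.shape[1]):
                pts.append(GroundTruthPoint(grid.cell_center(r, c),
                                            CLIFF if truth[r, c] else NON_CLIFF, "0"))
        return pts

    def test_map_equals_truth(self):
        truth = np.random.default_rng(0).random((6, 6)) < 0.5
        g = self.grid(truth)
        cm = evaluate(g, self.points_from(g, truth))
        assert cm.fn == 0 and cm.fp == 0
        assert cm.tp == truth.sum() and cm.tn == (~truth).sum()

    def test_map_is_complement_of_truth(self):
        truth = np.random.default_rng(1).random((6, 6)) < 0.5
        g = self.grid(~truth)
        cm = evaluate(g, self.points_from(g, truth))
        assert cm.tp == 0 and cm.tn == 0

    def test_random_pairs_vs_direct_count(self):
        rng = np.random.default_rng(2)
        truth = rng.random((7, 7)) < 0.4
        mapped = rng.random((7, 7)) < 0.6
        g = self.grid(mapped)
        cm = evaluate(g, self.points_from(g, truth))
        assert cm.tp == (truth & mapped).sum()
        assert cm.fn == (truth & ~mapped).sum()
        assert cm.fp == (~truth & mapped).sum()
        assert cm.tn == (~truth & ~mapped).sum()


class TestSampling:
    def setup_method(self):
        rng = np.random.default_rng(9)
        self.grid = RasterGrid(values=np.zeros((40, 70)), cell_size=10.0, nodata=None)
        self.truth = rng.random((40, 70)) < 0.5
        self.region = np.ones((40, 70), bool)
        # seven vertical strata
        self.strata = []
        for j in range(7):
            m = np.zeros((40, 70), bool)
            m[:, j * 10:(j + 1) * 10] = True
            self.strata.append(m)

    def test_seven_strata_hundred_points(self):
        pts = sample_ground_truth(self.grid, self.region, self.truth, 50, 50,
                                  self.strata, seed=1)
        assert len(pts) == 100
        assert sum(p.true_class == CLIFF for p in pts) == 50
        per_stratum = {s: 0 for s in map(str, range(7))}
        for p in pts:
            per_stratum[p.stratum] += 1
        assert set(per_stratum.values()) <= {14, 15}

    def test_no_cliff_points_requested(self):
        pts = sample_ground_truth(self.grid, self.region, self.truth, 0, 21,
                                  self.strata, seed=2)
        assert all(p.true_class == NON_CLIFF for p in pts)

    def test_deterministic_given_seed(self):
        a = sample_ground_truth(self.grid, self.region, self.truth, 20, 20, self.strata, seed=5)
        b = sample_ground_truth(self.grid, self.region, self.truth, 20, 20, self.strata, seed=5)
        assert [(p.position.x, p.position.y, p.true_class) for p in a] == \
               [(p.position.x, p.position.y, p.true_class) for p in b]

    def test_different_seeds_differ(self):
        sets = {
            tuple((p.position.x, p.position.y) for p in
                  sample_ground_truth(self.grid, self.region, self.truth, 20, 20,
                                      self.strata, seed=s))
            for s in range(20)
        }
        assert len(sets) > 1

    def test_sampling_without_replacement(self):
        pts = sample_ground_truth(self.grid, self.region, self.truth, 50, 50,
                                  self.strata, seed=3)
        assert len({(p.position.x, p.position.y) for p in pts}) == 100

    def test_infeasible_stratum_named(self):
        region = self.region.copy()
        region[:, 10:20] = False  # stratum 1 emptied
        with pytest.raises(InfeasibleSamplingError, match="stratum 1"):
            sample_ground_truth(self.grid, region, self.truth, 50, 50, self.strata, seed=1)
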