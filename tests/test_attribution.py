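"""Integrated gradients: exactness, completeness, consensus, thresholds."""

import math

import numpy as np
import pytest

import stfingerprint as sf
from stfingerprint.attribution import path_integrated_gradients
from stfingerprint.datamodel import CohortValidationError


class TestPathIntegral:
    @pytest.mark.parametrize("n_steps", [1, 3, 50])
    def test_linear_model_exact_at_any_step_count(self, n_steps):
        """For F(x) = sum w*x with zero baseline, attributions are
        exactly w_i * x_i regardless of the step count."""
        rng = np.random.default_rng(0)
        w = rng.normal(size=(4, 12))
        x = rng.normal(size=(4, 12))

        def grad_fn(batch):
            return np.broadcast_to(w, batch.shape).copy()

        ig = path_integrated_gradients(grad_fn, x, np.zeros_like(x), n_steps)
        np.testing.assert_allclose(ig, w * x, atol=1e-12)

    def test_input_equal_to_baseline_gives_zero(self, tiny_trained_model):
        model, cohort = tiny_trained_model
        s = cohort.subjects[0]
        baseline = s.timeseries.copy()
        site = model.site_onehot(s.site)

        def grad_fn(batch):
            return model.input_gradient(batch, site, 1)

        ig = path_integrated_gradients(grad_fn, s.timeseries, baseline, 16)
        np.testing.assert_array_equal(ig, 0.0)

    def test_midpoint_rule_converges_to_fine_riemann_oracle(self):
        """Per-cell agreement with a 100,000-step Riemann oracle on a
        small trained ReLU network: the discretisation error shrinks
        first-order in the step count (ReLU kinks along the path) and is
        below 1e-3 of the attribution scale by 800 steps."""
        cfg = sf.SynthConfig(n_class0=12, n_class1=6, n_regions=4,
                             planted_regions=(0,), nt_range=(24, 24),
                             n_sites=1, seed=31)
        cohort = sf.zscore_normalize(sf.generate_cohort(cfg))
        mcfg = sf.StDNNConfig(n_regions=4, conv_channels=(4, 3),
                              kernel_sizes=(5, 3), epochs=10, seed=32)
        model = sf.train(cohort, np.arange(len(cohort)), mcfg)
        s = cohort.subjects[0]
        fine = sf.integrated_gradients(
            model, s, sf.IGConfig(n_steps=100_000, target_class=1)).scores
        scale = np.abs(fine).max()
        errs = []
        for m in (50, 200, 800):
            coarse = sf.integrated_gradients(
                model, s, sf.IGConfig(n_steps=m, target_class=1)).scores
            errs.append(np.abs(coarse - fine).max() / scale)
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3

    def test_completeness_improves_with_steps(self, tiny_trained_model):
        """Attributions sum to F(x) - F(baseline); the mean relative gap
        shrinks as the Riemann discretisation is refined."""
        model, cohort = tiny_trained_model
        errs = []
        for n_steps in (8, 32, 128):
            rel = []
            for s in cohort.subjects[:6]:
                amap = sf.integrated_gradients(
                    model, s, sf.IGConfig(n_steps=n_steps, target_class=1))
                f_x = model.forward(s.timeseries,
                                    model.site_onehot(s.site))[1]
                f_0 = model.forward(np.zeros_like(s.timeseries),
                                    model.site_onehot(s.site))[1]
                rel.append(abs(amap.scores.sum() - (f_x - f_0))
                           / abs(f_x - f_0))
            errs.append(np.mean(rel))
        assert errs[0] > errs[1] > errs[2]


class TestConsensus:
    def _maps(self, arrays, fold=0):
        return {fold: [sf.AttributionMap(f"s{i}", a, 1)
                       for i, a in enumerate(arrays)]}

    def test_identical_maps_pass_through(self):
        a = np.arange(12.0).reshape(3, 4)
        maps = {f: [sf.AttributionMap(f"s{i}", a.copy(), 1)
                    for i in range(4)] for f in range(3)}
        table = sf.aggregate_group_features(maps, ["r0", "r1", "r2"])
        np.testing.assert_array_equal(table.median_scores, a)

    def test_median_robust_to_outlier(self):
        a = np.ones((2, 4))
        arrays = [a.copy() for _ in range(9)] + [a * 1e6]
        table = sf.aggregate_group_features(self._maps(arrays),
                                            ["r0", "r1"])
        np.testing.assert_array_equal(table.median_scores, a)

    def test_matches_brute_force_nested_median(self):
        rng = np.random.default_rng(8)
        maps = {f: [sf.AttributionMap(f"s{i}", rng.normal(size=(5, 7)), 1)
                    for i in range(6)] for f in range(4)}
        table = sf.aggregate_group_features(maps, [f"r{j}" for j in range(5)])
        expected = np.median(
            [np.median([m.scores for m in maps[f]], axis=0)
             for f in sorted(maps)], axis=0)
        np.testing.assert_allclose(table.median_scores, expected)

    def test_empty_fold_rejected(self):
        with pytest.raises(CohortValidationError):
            sf.aggregate_group_features({0: []}, ["r0"])


class TestTopFeatures:
    def _table(self, scores):
        return sf.FeatureScoreTable([scores], scores,
                                    [f"r{j}" for j in range(scores.shape[0])])

    def test_five_percent_of_246_by_200_is_2460_cells(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=(246, 200))
        table = sf.threshold_top_features(self._table(scores), 5.0)
        assert table.top_mask.sum() == 2460
        assert 2460 == math.ceil(0.05 * 246 * 200)

    def test_matches_sort_and_cut_oracle(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=(30, 40))
        table = sf.threshold_top_features(self._table(scores), 10.0)
        n_keep = math.ceil(0.10 * scores.size)
        cutoff = np.sort(scores.ravel())[::-1][n_keep - 1]
        np.testing.assert_array_equal(table.top_mask, scores >= cutoff)

    def test_dominant_region_ranks_first(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=(6, 50))
        scores[3] += 10.0
        table = sf.threshold_top_features(self._table(scores), 5.0)
        assert table.region_hits[0][0] == "r3"
        peaks = [h[2] for h in table.region_hits]
        assert peaks == sorted(peaks, reverse=True)

    def test_ties_expand_mask(self):
        scores = np.zeros((4, 10))
        scores[0, :5] = 1.0
        table = sf.threshold_top_features(self._table(scores), 10.0)
        # nominal keep = 4 cells, but 5 cells tie at the threshold value
        assert table.top_mask.sum() == 5

    def test_bad_percentile_rejected(self):
        with pytest.raises(CohortValidationError):
            sf.threshold_top_features(self._table(np.zeros((2, 10))), 0.0)


class TestRegionScores:
    def test_constant_and_antisymmetric_rows(self):
        scores = np.vstack([np.full(10, 3.5),
                            np.r_[np.arange(5), -np.arange(5)[::-1] - 0.0][::-1] * 0])
        scores[1] = np.r_[1.0, 2.0, -1.0, -2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        amap = sf.AttributionMap("s", scores, 1)
        out = sf.subject_region_scores(amap)
        assert out[0] == pytest.approx(3.5)
        assert out[1] == pytest.approx(0.0)

    def test_random_row_mean(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=(3, 20))
        out = sf.subject_region_scores(sf.AttributionMap("s", scores, 1))
        np.testing.assert_allclose(out, scores.sum(axis=1) / 20)
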