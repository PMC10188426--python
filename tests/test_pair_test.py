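"""CARP pipeline: splitting, regression, layering, composition, CRS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import carp
from carp.exceptions import (
    DegenerateScoresError,
    InsufficientDataError,
    InvalidParameterError,
)


class TestSplitSample:
    @pytest.mark.parametrize(
        "n,ell,expected_train",
        [(10, 0.5, 5), (500, 0.3, 150), (10, 0.25, 2), (7, 0.5, 3)],  # 3.5 rounds down
    )
    def test_train_size_rounds_half_down(self, n, ell, expected_train):
        split = carp.split_sample(n, ell, seed=0)
        assert split.n_train == expected_train
        assert split.n_test == n - expected_train

    def test_partition_is_disjoint_and_exhaustive(self):
        split = carp.split_sample(10, 0.5, seed=3)
        union = np.union1d(split.train_indices, split.test_indices)
        np.testing.assert_array_equal(union, np.arange(10))
        assert np.intersect1d(split.train_indices, split.test_indices).size == 0

    def test_seeded_determinism(self):
        a = carp.split_sample(100, 0.3, seed=11)
        b = carp.split_sample(100, 0.3, seed=11)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)

    @pytest.mark.parametrize("n,ell", [(10, 0.01), (10, 0.999), (100, 0.0), (100, 1.0)])
    def test_degenerate_splits_rejected(self, n, ell):
        with pytest.raises(InvalidParameterError):
            carp.split_sample(n, ell, seed=0)


class TestFitPairRegressions:
    def test_focal_coefficients_exactly_zero(self, rng):
        x = rng.integers(0, 2, (200, 6))
        w = carp.fit_pair_regressions(x, 2, 4)
        assert w.a_i[3] == 0.0 and w.a_i[5] == 0.0
        assert w.a_j[3] == 0.0 and w.a_j[5] == 0.0

    def test_constant_column_gets_zero_coefficient(self, rng):
        x = rng.integers(0, 2, (100, 5))
        x[:, 3] = 1  # constant predictor
        w = carp.fit_pair_regressions(x, 0, 1)
        assert w.a_i[4] == 0.0
        # intercept absorbs the constant: predictions unchanged vs dropping it
        preds = carp.predicted_sum(x, w)
        assert np.all(np.isfinite(preds))

    def test_recovers_exact_copy_relation(self, rng):
        # X_i == X_k exactly; other predictors independent noise
        n = 400
        x = rng.integers(0, 2, (n, 6))
        x[:, 0] = x[:, 3]
        w = carp.fit_pair_regressions(x, 0, 1)
        assert w.a_i[4] == pytest.approx(1.0, abs=1e-8)
        for k in (0, 3, 5, 6):
            assert w.a_i[k] == pytest.approx(0.0, abs=1e-8)

    def test_minimizes_training_mse(self, rng):
        """OLS predictions beat any perturbed weight vector on the training data."""
        x = rng.integers(0, 2, (150, 5))
        w = carp.fit_pair_regressions(x, 0, 1)
        y = x[:, 0].astype(float)
        pred = w.a_i[0] + x @ w.a_i[1:]
        base = np.mean((y - pred) ** 2)
        for bump in rng.normal(0, 0.05, size=(10, 3)):
            perturbed = w.a_i.copy()
            perturbed[[0, 3, 4]] += bump
            alt = np.mean((y - (perturbed[0] + x @ perturbed[1:])) ** 2)
            assert base <= alt + 1e-12

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            carp.fit_pair_regressions(np.ones((1, 4), dtype=int), 0, 1)


class TestPredictedSum:
    def test_zero_weights_give_constant(self):
        w = carp.PairWeights(
            a_i=np.r_[0.3, np.zeros(4)], a_j=np.r_[0.3, np.zeros(4)], focal=(0, 1)
        )
        out = carp.predicted_sum(np.zeros((7, 4), dtype=int), w)
        np.testing.assert_allclose(out, 0.6)

    def test_unit_weights_reduce_to_double_rest_score(self, rng):
        x = rng.integers(0, 2, (50, 5))
        a = np.r_[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]  # unit weights on items 3..5
        w = carp.PairWeights(a_i=a, a_j=a, focal=(0, 1))
        rest = x[:, 2:].sum(axis=1)
        np.testing.assert_allclose(carp.predicted_sum(x, w), 2.0 * rest)

    def test_matches_brute_force_dot_products(self, rng):
        x = rng.integers(0, 2, (30, 6))
        a_i = np.r_[rng.normal(size=7)]
        a_j = np.r_[rng.normal(size=7)]
        a_i[[1, 2]] = 0.0
        a_j[[1, 2]] = 0.0
        w = carp.PairWeights(a_i=a_i, a_j=a_j, focal=(0, 1))
        expected = [
            a_i[0] + a_j[0] + sum((a_i[1 + k] + a_j[1 + k]) * x[s, k] for k in range(6))
            for s in range(30)
        ]
        np.testing.assert_allclose(carp.predicted_sum(x, w), expected, atol=1e-12)


class TestQuantileSeparators:
    def test_distinct_scores_make_equal_layers(self):
        seps = carp.quantile_separators(np.arange(1, 101, dtype=float), m=10)
        np.testing.assert_array_equal(seps.q, [10, 20, 30, 40, 50, 60, 70, 80, 90])
        layers = carp.assign_layers(np.arange(1, 101, dtype=float), seps)
        assert np.all(np.bincount(layers)[1:] == 10)

    def test_few_distinct_values_collapse(self, rng):
        scores = rng.choice([0.0, 1.0, 2.0], size=100)
        seps = carp.quantile_separators(scores, m=10)
        assert seps.m_effective <= 3

    def test_constant_scores_error(self):
        with pytest.raises(DegenerateScoresError):
            carp.quantile_separators(np.full(50, 3.25), m=10)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(-50, 50), min_size=12, max_size=200).filter(
            lambda v: len(set(v)) > 1
        ),
        st.integers(2, 12),
    )
    def test_separators_strictly_increasing(self, scores, m):
        scores = np.asarray(scores)
        if scores.size < m:
            return
        seps = carp.quantile_separators(scores, m)
        assert np.all(np.diff(seps.q) > 0)
        layers = carp.assign_layers(scores, seps)
        assert layers.min() >= 1 and layers.max() <= seps.m_effective


class TestAssignLayers:
    def test_boundary_intervals(self):
        seps = carp.QuantileSeparators(q=np.array([0.5, 1.5]), m_requested=3)
        np.testing.assert_array_equal(carp.assign_layers([0.0, 1.0, 2.0], seps), [1, 2, 3])

    def test_exact_separator_value_falls_in_lower_layer(self):
        seps = carp.QuantileSeparators(q=np.array([1.0, 2.0]), m_requested=3)
        np.testing.assert_array_equal(carp.assign_layers([1.0, 2.0], seps), [1, 2])

    def test_every_score_gets_a_layer(self, rng):
        seps = carp.QuantileSeparators(q=np.array([-1.0, 0.0, 1.0]), m_requested=4)
        layers = carp.assign_layers(rng.normal(size=1000) * 10, seps)
        assert set(np.unique(layers)) <= {1, 2, 3, 4}


class TestCarpPairTest:
    def test_deterministic_given_seed(self, standard_55_bank):
        x = carp.simulate_responses(standard_55_bank, 1000, seed=4)
        a = carp.carp_pair_test(x, 0, 5, ell=0.3, seed=99)
        b = carp.carp_pair_test(x, 0, 5, ell=0.3, seed=99)
        assert a.z == b.z and a.p_value == b.p_value

    def test_focal_symmetry_whole_pipeline(self, standard_55_bank):
        x = carp.simulate_responses(standard_55_bank, 1500, seed=6)
        a = carp.carp_pair_test(x, 0, 5, ell=0.3, seed=7)
        b = carp.carp_pair_test(x, 5, 0, ell=0.3, seed=7)
        assert a.z == b.z

    def test_default_ell_rule(self):
        assert carp.default_ell(500) == 0.5
        assert carp.default_ell(501) == 0.3

    def test_training_sample_too_small(self, standard_55_bank):
        x = carp.simulate_responses(standard_55_bank, 30, seed=1)
        with pytest.raises(InsufficientDataError):
            carp.carp_pair_test(x, 0, 5, ell=0.2, seed=0)

    def test_reduction_to_rest_score_deciles(self, rng):
        """Equal positive weights layer identically to raw rest-score deciles."""
        x = rng.integers(0, 2, (600, 12))
        a = np.zeros(13)
        # equal dyadic weights on the non-focal items: the conditioning score
        # is exactly 0.5 * rest score in floating point, so the monotone-
        # transform comparison is free of summation-order noise
        a[3:] = 0.25
        w = carp.PairWeights(a_i=a, a_j=a, focal=(0, 1))
        train, test = x[:300], x[300:]
        weighted = carp.predicted_sum(train, w)
        rest = train[:, 2:].sum(axis=1).astype(float)
        seps_w = carp.quantile_separators(weighted, m=10)
        seps_r = carp.quantile_separators(rest, m=10)
        lw = carp.assign_layers(carp.predicted_sum(test, w), seps_w)
        lr = carp.assign_layers(test[:, 2:].sum(axis=1).astype(float), seps_r)
        np.testing.assert_array_equal(lw, lr)

    def test_no_decision_on_degenerate_scores(self):
        x = np.zeros((200, 4), dtype=int)
        x[:100, 0] = 1
        x[50:150, 1] = 1
        res = carp.carp_pair_test(x, 0, 1, ell=0.5, seed=0)
        assert res.mh is None and res.failure is not None
        assert not res.rejects(0.05)
        assert np.isnan(res.p_value)


class TestCrsPairTest:
    def test_focal_symmetry(self, standard_55_bank):
        x = carp.simulate_responses(standard_55_bank, 800, seed=12)
        assert carp.crs_pair_test(x, 0, 5).z == carp.crs_pair_test(x, 5, 0).z

    def test_layers_are_rest_scores(self, standard_55_bank):
        x = carp.simulate_responses(standard_55_bank, 300, seed=13)
        res = carp.crs_pair_test(x, 0, 5)
        rest = x.sum(axis=1) - x[:, 0] - x[:, 5]
        np.testing.assert_array_equal(res.conditioning, rest + 1)

    def test_type1_control_under_independent_items(self):
        """Zero-dimensional fair-coin items: rejection rate stays near alpha."""
        bank = carp.ItemBank(loadings=np.zeros((6, 1)), intercepts=np.zeros(6))
        reps, rejections = 400, 0
        for r in range(reps):
            x = carp.simulate_responses(bank, 1000, seed=5000 + r)
            rejections += carp.crs_pair_test(x, 0, 1).rejects(0.05)
        assert rejections / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
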