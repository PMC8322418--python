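"""Standardization, model scoring, greedy boosting, and model averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kboost import (
    ExpressionMatrix,
    InvalidParameterError,
    KBoostConfig,
    ModelRecord,
    PriorMatrix,
    TFIndex,
    bma_posterior,
    boost_gene,
    build_feature_library,
    default_shrinkage,
    fit_component,
    kboost,
    log_marginal_likelihood,
    log_model_prior,
    standardize_expression,
    variance_scaling,
)

from naive_reference import naive_kboost


def _matrix(values):
    G, n = np.asarray(values).shape
    return ExpressionMatrix(
        np.asarray(values, dtype=float),
        tuple(f"G{i}" for i in range(G)),
        tuple(f"S{i}" for i in range(n)),
    )


class TestStandardize:
    def test_rows_have_zero_mean_unit_variance(self, rng):
        X = standardize_expression(_matrix(rng.standard_normal((5, 9)) * 3 + 7))
        np.testing.assert_allclose(X.values.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(X.values.var(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_constant_gene_zeroed_and_flagged(self):
        X = standardize_expression(_matrix([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert X.constant_genes == {0}
        np.testing.assert_array_equal(X.values[0], 0.0)

    def test_idempotent(self, rng):
        X = _matrix(rng.standard_normal((4, 6)))
        once = standardize_expression(X)
        twice = standardize_expression(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)


class TestDefaultShrinkage:
    @pytest.mark.parametrize(
        "n,expected", [(24, 10.0 / 24.0), (100, 0.1), (10, 0.5), (11, 10.0 / 11.0), (3, 0.5)]
    )
    def test_sample_size_rule(self, n, expected):
        assert default_shrinkage(n) == pytest.approx(expected, abs=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            default_shrinkage(1)


class TestModelScores:
    def test_log_ml_closed_form(self):
        assert log_marginal_likelihood(1.0, 17) == 0.0
        assert log_marginal_likelihood(np.e, 25) == pytest.approx(-12.0)
        # halving the RSS at n=21 raises the log-ML by 10 ln 2
        delta = log_marginal_likelihood(0.5, 21) - log_marginal_likelihood(1.0, 21)
        assert delta == pytest.approx(10.0 * np.log(2.0))

    def test_log_ml_clamps_perfect_fits(self):
        assert np.isfinite(log_marginal_likelihood(0.0, 50))

    def test_uniform_prior_is_subset_independent(self):
        w = np.full(6, 0.5)
        vals = {log_model_prior(m, w) for m in [(), (0,), (1, 3), (0, 1, 2, 3, 4, 5)]}
        assert len(vals) == 1
        assert vals.pop() == pytest.approx(6.0 * np.log(0.5))

    def test_informative_prior_log_odds(self):
        w = np.array([0.6])
        diff = log_model_prior((0,), w) - log_model_prior((), w)
        assert diff == pytest.approx(np.log(0.6) - np.log(0.4))

    def test_repeated_members_count_once(self):
        w = np.array([0.3, 0.7])
        assert log_model_prior((1, 1), w) == log_model_prior((1,), w)

    def test_weights_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidParameterError):
            log_model_prior((0,), np.array([1.0]))


class TestFitComponent:
    def test_orthogonal_residual_gives_zero(self, rng):
        g = np.eye(6)[:, :2]
        residual = np.array([0.0, 0.0, 1.0, -2.0, 3.0, 0.5])
        beta, pred = fit_component(g, residual, nu=0.7)
        np.testing.assert_allclose(beta, 0.0)
        np.testing.assert_allclose(pred, 0.0)

    def test_exact_fit_with_full_shrinkage(self):
        g = np.ones((4, 1)) / 2.0
        residual = 2.0 * g[:, 0]
        beta, pred = fit_component(g, residual, nu=1.0)
        np.testing.assert_allclose(pred, residual, atol=1e-12)

    def test_nu_one_matches_least_squares_oracle(self, rng):
        A = rng.standard_normal((8, 3))
        q, _ = np.linalg.qr(A)
        y = rng.standard_normal(8)
        _, pred = fit_component(q, y, nu=1.0)
        rss = np.sum((y - pred) ** 2)
        beta_ls, res_ls, *_ = np.linalg.lstsq(q, y, rcond=None)
        rss_oracle = np.sum((y - q @ beta_ls) ** 2)
        assert rss == pytest.approx(rss_oracle, abs=1e-8)
        # closed form used internally: ||y||^2 - ||q^T y||^2
        assert rss == pytest.approx(y @ y - np.sum((q.T @ y) ** 2), abs=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(Exception):
            fit_component(np.ones((4, 1)), np.ones(5), 0.5)


class TestBoostGene:
    def _lib(self, X, tfs):
        return build_feature_library(standardize_expression(X), tfs)

    def test_record_count_is_iterations_times_candidates(self, small_expression, small_tfs):
        Xs = standardize_expression(small_expression)
        lib = build_feature_library(Xs, small_tfs)
        cfg = KBoostConfig(nu=0.5, iterations=3)
        records = boost_gene(5, lib, Xs.values[5], np.full(3, 0.5), cfg)
        assert len(records) == 3 * 3
        # a TF gene never proposes itself
        records_tf = boost_gene(1, lib, Xs.values[1], np.full(3, 0.5), cfg)
        assert len(records_tf) == 3 * 2
        assert all(1 not in r.members for r in records_tf)

    def test_planted_regulator_selected_first(self, rng):
        n = 30
        values = rng.standard_normal((5, n))
        values[4] = 1.3 * values[2] + 0.01 * rng.standard_normal(n)
        X = standardize_expression(_matrix(values))
        lib = build_feature_library(X, TFIndex((0, 1, 2)))
        records = boost_gene(4, lib, X.values[4], np.full(3, 0.5), KBoostConfig())
        singletons = [r for r in records if len(r.members) == 1]
        best = min(singletons, key=lambda r: r.rss)
        assert best.members == (2,)

    def test_no_candidates_yields_empty(self, small_expression):
        Xs = standardize_expression(small_expression)
        lib = build_feature_library(Xs, TFIndex((3,)))
        assert boost_gene(3, lib, Xs.values[3], np.full(1, 0.5), KBoostConfig()) == []


class TestBMA:
    def _rec(self, members, log_ml, log_prior=0.0):
        return ModelRecord(0, tuple(members), 1.0, log_ml, log_prior)

    def test_symmetric_singletons_split_evenly(self):
        records = [self._rec((0,), -1.0), self._rec((1,), -1.0)]
        np.testing.assert_allclose(bma_posterior(records, 2), [0.5, 0.5])

    def test_hand_normalized_three_model_average(self):
        # log-posteriors {0, -ln2, -ln2} -> weights {1/2, 1/4, 1/4}
        records = [
            self._rec((0,), 0.0),
            self._rec((1,), -np.log(2.0)),
            self._rec((0, 1), -np.log(2.0)),
        ]
        np.testing.assert_allclose(bma_posterior(records, 2), [0.75, 0.5])

    def test_weights_sum_to_one(self, small_expression, small_tfs, rng):
        Xs = standardize_expression(small_expression)
        lib = build_feature_library(Xs, small_tfs)
        records = boost_gene(6, lib, Xs.values[6], np.full(3, 0.5), KBoostConfig())
        log_posts = np.array([r.log_ml + r.log_prior for r in records])
        from scipy.special import logsumexp

        weights = np.exp(log_posts - logsumexp(log_posts))
        assert weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_no_underflow_at_large_n(self):
        # log-ML magnitudes of order (n-1)/2 * ln(rss) for n = 10^4
        records = [
            self._rec((0,), -5000.0 * np.log(3.0)),
            self._rec((1,), -5000.0 * np.log(3.1)),
        ]
        out = bma_posterior(records, 2)
        assert np.all(out > 0) and np.all(out <= 1)

    def test_shifting_all_log_priors_is_invariant(self, rng):
        members = [(0,), (1,), (0, 1), (1, 1)]
        base = [self._rec(m, float(lm)) for m, lm in zip(members, rng.standard_normal(4))]
        shifted = [
            ModelRecord(0, r.members, r.rss, r.log_ml, r.log_prior + 17.3) for r in base
        ]
        np.testing.assert_allclose(
            bma_posterior(base, 2), bma_posterior(shifted, 2), atol=1e-12
        )

    def test_raising_an_edge_weight_never_lowers_its_posterior(self, rng):
        members = [(0,), (1,), (0, 1)]
        rss = [0.7, 0.9, 0.5]
        n = 12

        def posts(w0):
            w = np.array([w0, 0.5])
            recs = [
                ModelRecord(
                    0, m, r, log_marginal_likelihood(r, n), log_model_prior(m, w)
                )
                for m, r in zip(members, rss)
            ]
            return bma_posterior(recs, 2)

        values = [posts(w0)[0] for w0 in np.linspace(0.05, 0.95, 10)]
        assert np.all(np.diff(values) >= -1e-12)

    def test_empty_records_zero_vector(self):
        np.testing.assert_array_equal(bma_posterior([], 4), np.zeros(4))


class TestVarianceScaling:
    def test_constant_column_vanishes(self):
        raw = np.column_stack([np.full(5, 0.3), np.linspace(0, 1, 5)])
        scaled = variance_scaling(raw)
        np.testing.assert_array_equal(scaled[:, 0], 0.0)

    def test_two_entry_hand_computation(self):
        scaled = variance_scaling(np.array([[0.0], [1.0]]))
        np.testing.assert_allclose(scaled, [[0.0], [0.5]])

    def test_column_order_preserved(self, rng):
        raw = rng.uniform(size=(20, 4))
        scaled = variance_scaling(raw)
        for p in range(4):
            np.testing.assert_array_equal(
                np.argsort(raw[:, p]), np.argsort(scaled[:, p])
            )


class TestKBoost:
    def test_deterministic(self, small_expression, small_tfs):
        a = kboost(small_expression, small_tfs)
        b = kboost(small_expression, small_tfs)
        assert np.array_equal(a.raw, b.raw) and np.array_equal(a.scaled, b.scaled)

    def test_bounds_self_loops_and_scaling_cap(self, small_expression, small_tfs):
        post = kboost(small_expression, small_tfs)
        assert np.all((post.raw >= 0) & (post.raw <= 1))
        assert np.all((post.scaled >= 0) & (post.scaled <= 0.25))
        for p, row in enumerate(post.tf_rows):
            assert post.raw[row, p] == 0.0

    def test_shape_mismatch_names_dimensions(self, small_expression, small_tfs):
        from kboost import ShapeError

        with pytest.raises(ShapeError, match="G=8"):
            kboost(small_expression, small_tfs, PriorMatrix.uniform(4, 3))

    def test_uniform_prior_value_is_irrelevant(self, small_expression, small_tfs):
        """With a constant-w prior, only subset size matters; with w=0.5 the
        prior cancels entirely, and raw must equal the all-0.5 default."""
        default = kboost(small_expression, small_tfs)
        explicit = kboost(
            small_expression, small_tfs, PriorMatrix.uniform(8, 3, 0.5)
        )
        np.testing.assert_array_equal(default.raw, explicit.raw)

    def test_constant_gene_row_is_zero(self, rng, small_tfs):
        values = rng.standard_normal((8, 12))
        values[6] = 2.0
        post = kboost(_matrix(values), small_tfs)
        np.testing.assert_array_equal(post.raw[6], 0.0)

    def test_excluded_tf_column_is_zero(self, rng):
        values = rng.standard_normal((8, 12))
        values[1] = -1.0
        post = kboost(_matrix(values), TFIndex((0, 1, 2)))
        assert post.excluded_tfs == {1}
        np.testing.assert_array_equal(post.raw[:, 1], 0.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        G, n, P = 7, 12, 3
        values = rng.standard_normal((G, n))
        tfs = TFIndex(tuple(range(P)))
        W = rng.uniform(0.2, 0.8, size=(G, P))
        post = kboost(_matrix(values), tfs, PriorMatrix(W))
        raw_ref, scaled_ref = naive_kboost(values, tuple(range(P)), W)
        np.testing.assert_allclose(post.raw, raw_ref, atol=1e-8)
        np.testing.assert_allclose(post.scaled, scaled_ref, atol=1e-8)


class TestShrinkageFlattening:
    def test_smaller_nu_moves_rss_toward_total_variance(self, rng):
        """As nu -> 0 every singleton fit explains less, RSS -> ||x||^2, and
        posterior differences between TFs flatten."""
        y = rng.standard_normal(10)
        q, _ = np.linalg.qr(rng.standard_normal((10, 2)))
        total = y @ y
        rss = []
        for nu in [1.0, 0.5, 0.1, 0.01]:
            _, pred = fit_component(q, y, nu)
            rss.append(np.sum((y - pred) ** 2))
        assert np.all(np.diff(rss) > 0)
        assert rss[-1] == pytest.approx(total, rel=0.05)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_bma_weights_normalized_property(seed):
    """BMA entries stay in [0,1] and per-record weights sum to 1 for random
    explored sets."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 8))
    P = int(rng.integers(2, 5))
    records = [
        ModelRecord(
            0,
            tuple(int(i) for i in rng.integers(0, P, size=rng.integers(1, 4))),
            1.0,
            float(rng.normal(scale=5)),
            float(rng.normal()),
        )
        for _ in range(k)
    ]
    out = bma_posterior(records, P)
    assert np.all((out >= 0) & (out <= 1 + 1e-12))
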