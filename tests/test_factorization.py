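"""Core factorization: initialization, objective terms, updates, fit loop."""

import numpy as np
import pytest

from topconnmf import (
    FactorConfig,
    FactorPair,
    fit,
    floor_nonfinite,
    initialize_factors,
    l21_norm,
    reconstruction_error,
    total_cost,
    update_basis,
    update_coefficients,
)
from topconnmf.errors import DimensionError, InvalidRankError
from topconnmf.topology import topology_penalty


class TestInitializeFactors:
    def test_deterministic_given_seed(self, rng):
        X = rng.random((6, 9))
        a = initialize_factors(X, 3, seed=7)
        b = initialize_factors(X, 3, seed=7)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.H, b.H)

    def test_rank_out_of_bounds_rejected(self, rng):
        X = rng.random((6, 9))
        with pytest.raises(InvalidRankError):
            initialize_factors(X, 7, seed=0)
        with pytest.raises(InvalidRankError):
            initialize_factors(X, 0, seed=0)

    def test_scaling_rule(self):
        # X of mean 4, k=1: scale sqrt(4/1)=2, entries in (0, 2]
        X = np.full((5, 5), 4.0)
        F = initialize_factors(X, 1, seed=0)
        for M in (F.W, F.H):
            assert np.all(M > 0) and np.all(M <= 2.0)


class TestObjectiveTerms:
    def test_reconstruction_error_exact_and_zero_factors(self, rng):
        W = rng.random((4, 2))
        H = rng.random((2, 5))
        assert reconstruction_error(W @ H, FactorPair(W, H)) == pytest.approx(0.0)
        F0 = FactorPair(np.zeros((2, 1)), np.zeros((1, 2)))
        assert reconstruction_error(np.eye(2), F0) == pytest.approx(np.sqrt(2))

    def test_reconstruction_error_matches_elementwise_oracle(self, rng):
        X = rng.random((5, 7))
        F = FactorPair(rng.random((5, 3)), rng.random((3, 7)))
        R = X - F.W @ F.H
        oracle = np.sqrt(sum(R[i, j] ** 2 for i in range(5) for j in range(7)))
        assert reconstruction_error(X, F) == pytest.approx(oracle, rel=1e-12)

    def test_reconstruction_error_shape_mismatch(self, rng):
        with pytest.raises(DimensionError):
            reconstruction_error(rng.random((4, 4)), FactorPair(rng.random((3, 2)), rng.random((2, 4))))

    @pytest.mark.parametrize(
        "W,expected",
        [([[3.0, 4.0], [0.0, 0.0]], 5.0), (np.eye(2), 2.0)],
    )
    def test_l21_norm_hand_cases(self, W, expected):
        assert l21_norm(np.asarray(W)) == pytest.approx(expected)

    def test_l21_norm_matches_row_loop_oracle(self, rng):
        W = rng.standard_normal((6, 3))
        oracle = sum(np.sqrt(np.sum(W[i] ** 2)) for i in range(6))
        assert l21_norm(W) == pytest.approx(oracle, rel=1e-12)

    def test_total_cost_decomposes_into_terms(self, rng):
        X = rng.random((6, 10))
        F = FactorPair(rng.random((6, 3)) + 0.1, rng.random((3, 10)) + 0.1)
        cfg = FactorConfig(k=3, alpha=0.2, beta=0.3)
        T, _ = topology_penalty(F.H, 3, cfg.floor_eps)
        expected = reconstruction_error(X, F) + 0.2 * l21_norm(F.W) + 0.3 * T
        assert total_cost(X, F, cfg) == pytest.approx(expected, rel=1e-12)
        cfg0 = FactorConfig(k=3, alpha=0.0, beta=0.0)
        assert total_cost(F.W @ F.H, F, cfg0) == pytest.approx(0.0, abs=1e-9)


class TestFloorNonfinite:
    def test_nan_and_inf_replaced(self):
        M = np.array([[np.nan, 1.0], [np.inf, 2.0]])
        out = floor_nonfinite(M, 1e-10)
        assert np.array_equal(out, [[1e-10, 1.0], [1e-10, 2.0]])

    def test_positive_matrix_unchanged_and_zeros_floored(self, rng):
        M = rng.random((3, 3)) + 0.5
        assert np.array_equal(floor_nonfinite(M, 1e-10), M)
        assert np.all(floor_nonfinite(np.zeros((2, 2)), 1e-10) == 1e-10)


class TestUpdates:
    def test_fixed_point_of_exact_factorization(self, rng):
        W = rng.random((5, 3)) + 0.2
        H = rng.random((3, 8)) + 0.2
        X = W @ H
        cfg = FactorConfig(k=3, alpha=0.0, beta=0.0)
        F = FactorPair(W, H)
        np.testing.assert_allclose(update_basis(X, F, cfg), W, rtol=1e-10)
        np.testing.assert_allclose(update_coefficients(X, F, cfg), H, rtol=1e-10)

    def test_scalar_hand_case(self):
        cfg = FactorConfig(k=1, alpha=0.0, beta=0.0)
        F = FactorPair(np.array([[1.0]]), np.array([[1.0]]))
        X = np.array([[2.0]])
        assert update_basis(X, F, cfg)[0, 0] == pytest.approx(2.0)
        assert update_coefficients(X, F, cfg)[0, 0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_updates_preserve_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((8, 12))
        cfg = FactorConfig(k=3, seed=seed)
        F = initialize_factors(X, 3, seed)
        for _ in range(5):
            W = update_basis(X, F, cfg)
            F = FactorPair(W, F.H)
            H = update_coefficients(X, F, cfg)
            F = FactorPair(W, H)
            assert np.all(F.W >= 0) and np.all(F.H >= 0)
            assert np.all(np.isfinite(F.W)) and np.all(np.isfinite(F.H))


class TestFit:
    def test_deterministic_given_seed(self, rng):
        X = rng.random((10, 14))
        cfg = FactorConfig(k=3, max_iter=40, seed=5)
        a = fit(X, cfg)
        b = fit(X, cfg)
        assert a.cost_trace == b.cost_trace
        assert np.array_equal(a.factors.W, b.factors.W)

    def test_trace_bookkeeping_and_convergence_flag(self, rng):
        X = rng.random((10, 14))
        res = fit(X, FactorConfig(k=3, max_iter=200, tol=1e-6, seed=1))
        assert len(res.cost_trace) == res.n_iter == len(res.re_trace)
        if res.converged:
            c = res.cost_trace
            rel = abs(c[-1] - c[-2]) / max(c[-2], 1e-10)
            assert rel < 1e-6

    def test_invalid_rank_rejected(self, rng):
        X = rng.random((4, 6))
        with pytest.raises(InvalidRankError):
            fit(X, FactorConfig(k=5))

    def test_unregularized_cost_descent_short(self, rng):
        """Classical-NMF limit: cost is non-increasing without penalties."""
        X = rng.random((12, 20))
        res = fit(X, FactorConfig(k=3, alpha=0.0, beta=0.0, max_iter=80, tol=1e-300, seed=2))
        c = np.asarray(res.cost_trace)
        assert np.all(np.diff(c) <= c[:-1] * 1e-8 + 1e-12)

    def test_regularized_cost_descent_short(self):
        """Default penalties: total cost non-increasing over 80 iterations."""
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            X = rng.random((20, 40)) * 2.0
            res = fit(X, FactorConfig(k=3, max_iter=80, tol=1e-300, seed=seed))
            c = np.asarray(res.cost_trace)
            assert np.all(np.diff(c) <= c[:-1] * 1e-8), f"ascent at seed {seed}"
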