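import warnings

import numpy as np
import pytest

from sefreq import (
    DecompositionConfig,
    FrequencyMatrix,
    ValidationError,
    fit,
    kkt_residual,
    loss,
    normalize_rows_h,
    predict_scores,
    update_step,
)
from sefreq.decomposition import ConvergenceWarning, initial_factors

from conftest import random_sparse_matrix
from oracles import finite_diff_grads, weighted_loss


class TestLoss:
    def test_zero_factors_leave_observed_term(self, tiny_matrix):
        W = np.zeros((2, 1))
        H = np.zeros((1, 2))
        assert loss(tiny_matrix, W, H, 0.5) == pytest.approx(0.5 * (25 + 16))

    def test_exact_fit_is_zero(self):
        W = np.array([[1.0], [2.0]])
        H = np.array([[2.0, 0.0]])
        fm = FrequencyMatrix(np.array([[2, 0], [4, 0]]), ["a", "b"], ["x", "y"])
        assert loss(fm, W, H, 0.3) == pytest.approx(0.0)

    def test_hand_computed_value(self, tiny_matrix):
        W = np.array([[1.0], [1.0]])
        H = np.array([[1.0, 1.0]])
        # ½((5−1)² + (4−1)²) + 0.025·(1² + 1²)
        assert loss(tiny_matrix, W, H, 0.05) == pytest.approx(12.55)

    def test_negative_factors_rejected(self, tiny_matrix):
        with pytest.raises(ValidationError):
            loss(tiny_matrix, np.array([[-1.0], [1.0]]), np.array([[1.0, 1.0]]), 0.05)

    def test_matches_weighted_residual_form(self, small_random_matrix):
        rng = np.random.default_rng(0)
        W = rng.uniform(0, 1, (12, 3))
        H = rng.uniform(0, 1, (3, 9))
        for alpha in (0.0, 0.05, 1.0):
            assert loss(small_random_matrix, W, H, alpha) == pytest.approx(
                float(weighted_loss(small_random_matrix.values, W, H, alpha))
            )


class TestUpdateStep:
    def test_fixed_point_at_exact_fit(self):
        W = np.array([[1.0], [2.0]])
        H = np.array([[2.0, 1.0]])
        product = W @ H
        fm = FrequencyMatrix(np.round(product).astype(int), ["a", "b"], ["x", "y"])
        W2, H2 = update_step(fm, W, H, alpha=0.05)
        np.testing.assert_allclose(W2, W, rtol=1e-9)
        np.testing.assert_allclose(H2, H, rtol=1e-9)

    def test_zero_row_is_absorbing(self, small_random_matrix):
        rng = np.random.default_rng(1)
        W = rng.uniform(0.1, 1, (12, 3))
        W[4] = 0.0
        H = rng.uniform(0.1, 1, (3, 9))
        W2, _ = update_step(small_random_matrix, W, H, alpha=0.05)
        assert np.all(W2[4] == 0.0)

    def test_hand_arithmetic_2x2(self, tiny_matrix):
        # brute-force check of all updated entries on the 2×2 instance
        W = np.array([[1.0], [1.0]])
        H = np.array([[1.0, 1.0]])
        alpha = 0.05
        R = tiny_matrix.values.astype(float)
        obs = R > 0
        # W rule with H fixed
        W_exp = np.zeros_like(W)
        for i in range(2):
            num = sum(R[i, j] * H[0, j] for j in range(2))
            den = sum(
                (1.0 if obs[i, j] else alpha) * (W[i, 0] * H[0, j]) * H[0, j]
                for j in range(2)
            )
            W_exp[i, 0] = W[i, 0] * num / den
        assert W_exp[0, 0] == pytest.approx(5.0 / 1.05)  # ≈ 4.7619
        # H rule with the *updated* W
        H_exp = np.zeros_like(H)
        for j in range(2):
            num = sum(W_exp[i, 0] * R[i, j] for i in range(2))
            den = sum(
                W_exp[i, 0] * (1.0 if obs[i, j] else alpha) * (W_exp[i, 0] * H[0, j])
                for i in range(2)
            )
            H_exp[0, j] = H[0, j] * num / den
        W2, H2 = update_step(tiny_matrix, W, H, alpha=alpha)
        np.testing.assert_allclose(W2, W_exp, rtol=1e-9)
        np.testing.assert_allclose(H2, H_exp, rtol=1e-9)

    def test_never_increases_loss(self, small_random_matrix):
        rng = np.random.default_rng(2)
        W = rng.uniform(0, 0.5, (12, 4))
        H = rng.uniform(0, 0.5, (4, 9))
        for alpha in (0.0, 0.05, 0.5, 1.0):
            l0 = loss(small_random_matrix, W, H, alpha)
            W2, H2 = update_step(small_random_matrix, W, H, alpha)
            assert loss(small_random_matrix, W2, H2, alpha) <= l0 * (1 + 1e-12)
            assert np.min(W2) >= 0 and np.min(H2) >= 0

    def test_efficient_denominator_matches_literal_form(self, small_random_matrix):
        rng = np.random.default_rng(3)
        W = rng.uniform(0.1, 1, (12, 3))
        H = rng.uniform(0.1, 1, (3, 9))
        alpha, eps = 0.3, 1e-16
        R = small_random_matrix.values.astype(float)
        Mobs = (R > 0).astype(float)
        Mzero = 1.0 - Mobs
        P = W @ H
        W_lit = W * (R @ H.T) / ((Mobs * P) @ H.T + alpha * (Mzero * P) @ H.T + eps)
        P2 = W_lit @ H
        H_lit = H * (W_lit.T @ R) / (
            W_lit.T @ (Mobs * P2) + alpha * (W_lit.T @ (Mzero * P2)) + eps
        )
        W2, H2 = update_step(small_random_matrix, W, H, alpha, eps)
        np.testing.assert_allclose(W2, W_lit, rtol=1e-12)
        np.testing.assert_allclose(H2, H_lit, rtol=1e-12)


class TestNormalization:
    def test_three_four_five(self):
        W = np.array([[2.0], [1.0]])
        H = np.array([[3.0, 4.0]])
        W2, H2 = normalize_rows_h(W, H)
        np.testing.assert_allclose(H2, [[0.6, 0.8]])
        np.testing.assert_allclose(W2, [[10.0], [5.0]])

    def test_unit_rows_unchanged(self):
        H = np.array([[0.6, 0.8], [1.0, 0.0]])
        W = np.ones((3, 2))
        W2, H2 = normalize_rows_h(W, H)
        np.testing.assert_allclose(H2, H)
        np.testing.assert_allclose(W2, W)

    def test_compensated_mode_preserves_product(self):
        rng = np.random.default_rng(4)
        W = rng.uniform(0.1, 2, (5, 2))
        H = rng.uniform(0.1, 2, (2, 3))
        W2, H2 = normalize_rows_h(W, H, compensate=True)
        np.testing.assert_allclose(W2 @ H2, W @ H, rtol=1e-14)
        np.testing.assert_allclose(np.linalg.norm(H2, axis=1), 1.0)

    def test_zero_row_skipped(self):
        H = np.array([[0.0, 0.0], [3.0, 4.0]])
        W = np.ones((2, 2))
        _, H2 = normalize_rows_h(W, H)
        assert np.all(H2[0] == 0.0)


class TestFit:
    def test_all_zero_matrix_drives_product_to_zero(self):
        fm = FrequencyMatrix(np.zeros((6, 5), dtype=int), list("abcdef"), list("vwxyz"))
        model = fit(fm, DecompositionConfig(k=2, alpha=0.5, seed=0, max_iter=2000))
        assert model.loss_trace[-1] < 1e-8
        assert float(np.abs(predict_scores(model)).max()) < 1e-3

    def test_rank1_exact_recovery(self):
        fm = FrequencyMatrix(np.array([[1, 2], [2, 4]]), ["a", "b"], ["x", "y"])
        model = fit(
            fm, DecompositionConfig(k=1, alpha=0.05, seed=0, tol_x=1e-10, max_iter=50_000)
        )
        assert model.loss_trace[-1] < 1e-6
        np.testing.assert_allclose(predict_scores(model), [[1, 2], [2, 4]], atol=1e-3)

    def test_loss_trace_monotone_compensated(self, small_random_matrix):
        model = fit(small_random_matrix, DecompositionConfig(k=3, seed=7, max_iter=400))
        diffs = np.diff(model.loss_trace)
        assert np.all(diffs <= 1e-10 * model.loss_trace[:-1] + 1e-12)

    def test_loss_trace_monotone_h_only_mode(self, small_random_matrix):
        model = fit(
            small_random_matrix,
            DecompositionConfig(k=3, seed=7, max_iter=400, normalization="h_only"),
        )
        diffs = np.diff(model.loss_trace[2:])
        assert np.all(diffs <= 1e-8 * model.loss_trace[2:-1] + 1e-10)

    def test_max_iter_warns_and_records_reason(self, small_random_matrix):
        with pytest.warns(ConvergenceWarning):
            model = fit(small_random_matrix, DecompositionConfig(k=3, seed=0, max_iter=5))
        assert model.stop_reason.startswith("max_iter")
        assert model.n_iter == 5

    def test_deterministic_given_seed(self, small_random_matrix):
        m1 = fit(small_random_matrix, DecompositionConfig(k=3, seed=11, max_iter=100))
        m2 = fit(small_random_matrix, DecompositionConfig(k=3, seed=11, max_iter=100))
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.H, m2.H)

    def test_k_must_be_small(self, tiny_matrix):
        with pytest.raises(ValidationError):
            fit(tiny_matrix, DecompositionConfig(k=2))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            DecompositionConfig(alpha=1.5)
        with pytest.raises(ValidationError):
            DecompositionConfig(k=0)


class TestPredictScores:
    @pytest.mark.parametrize(
        "w, h, expected", [((1, 0), (0, 1), 0.0), ((1, 2), (3, 1), 5.0)]
    )
    def test_dot_products(self, w, h, expected):
        W = np.array([list(w)], dtype=float)
        H = np.array([list(h)], dtype=float).T
        assert float((W @ H)[0, 0]) == pytest.approx(expected)

    def test_consistent_with_loss(self, tiny_matrix):
        W = np.array([[1.0], [1.0]])
        H = np.array([[1.0, 1.0]])
        P = W @ H
        obs = tiny_matrix.values > 0
        recomputed = 0.5 * np.sum(
            (tiny_matrix.values[obs] - P[obs]) ** 2
        ) + 0.025 * np.sum(P[~obs] ** 2)
        assert loss(tiny_matrix, W, H, 0.05) == pytest.approx(float(recomputed))


class TestKKTResidual:
    def test_gradients_match_finite_differences(self, small_random_matrix):
        rng = np.random.default_rng(5)
        W = rng.uniform(0.2, 1, (12, 2))
        H = rng.uniform(0.2, 1, (2, 9))
        alpha = 0.3
        gW, gH = finite_diff_grads(small_random_matrix.values.astype(float), W, H, alpha)
        # with strictly positive factors the residual equals the max |grad| where
        # grad < factor, so compare against the numeric gradients directly
        R = small_random_matrix.values.astype(float)
        obs = R > 0
        P = W @ H
        D = np.where(obs, P - R, alpha * P)
        np.testing.assert_allclose(D @ H.T, gW, rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(W.T @ D, gH, rtol=1e-5, atol=1e-6)

    def test_positive_at_random_point(self, small_random_matrix):
        rng = np.random.default_rng(6)
        W = rng.uniform(0.5, 1, (12, 2))
        H = rng.uniform(0.5, 1, (2, 9))
        assert kkt_residual(small_random_matrix, W, H, 0.05) > 0.1

    def test_small_after_tight_fit(self):
        rng = np.random.default_rng(7)
        fm = random_sparse_matrix(rng, 10, 8, density=0.5)
        cfg = DecompositionConfig(k=2, seed=3, tol_x=1e-9, max_iter=60_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = fit(fm, cfg)
        r0 = kkt_residual(fm, *initial_factors(10, 8, cfg), 0.05)
        r1 = kkt_residual(fm, model.W, model.H, 0.05)
        assert r1 < 1e-2 * r0
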