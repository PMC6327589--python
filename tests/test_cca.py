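"""CCA core: K matrix, signed SVD, end-to-end fits, regression view."""

import numpy as np
import pytest

from whitecca import (
    JointMoments,
    RankDeficiencyError,
    cca_fit,
    compute_K,
    compute_K_lowrank,
    delta_mse,
    fit_shrinkage_model,
    optimal_linear_predictor,
    scores,
    shrink_intensity,
    svd_signed,
)
from conftest import random_joint_correlation, random_psd


def classical_cca_eigen_oracle(X, Y):
    """|lambda_i| from the classical generalized eigenproblem on empirical S."""
    n = X.shape[0]
    Z = np.hstack([X, Y])
    Zc = Z - Z.mean(0)
    S = Zc.T @ Zc / (n - 1)
    p = X.shape[1]
    Sx, Sy, Sxy = S[:p, :p], S[p:, p:], S[:p, p:]
    M = np.linalg.solve(Sx, Sxy) @ np.linalg.solve(Sy, Sxy.T)
    ev = np.linalg.eigvals(M).real
    ev = np.clip(ev, 0.0, None)
    return np.sort(np.sqrt(ev))[::-1][: min(X.shape[1], Y.shape[1])]


class TestComputeK:
    def test_identity_within_set(self):
        P_XY = np.diag([0.5, -0.3])
        np.testing.assert_allclose(
            compute_K(np.eye(2), P_XY, np.eye(2)), P_XY, atol=1e-14
        )

    def test_scalar_case(self):
        assert compute_K([[1.0]], [[0.42]], [[1.0]])[0, 0] == pytest.approx(0.42)

    def test_dense_oracle(self, rng):
        P_X, P_XY, P_Y = random_joint_correlation(rng, 4, 3)
        wx, Gx = np.linalg.eigh(P_X)
        wy, Gy = np.linalg.eigh(P_Y)
        oracle = ((Gx / np.sqrt(wx)) @ Gx.T) @ P_XY @ ((Gy / np.sqrt(wy)) @ Gy.T)
        np.testing.assert_allclose(compute_K(P_X, P_XY, P_Y), oracle, atol=1e-10)
        # singular values of K are bounded by one for a PSD joint correlation
        assert np.linalg.svd(oracle, compute_uv=False).max() <= 1 + 1e-10


class TestComputeKLowrank:
    @staticmethod
    def _models(X, Y, lam):
        mx = fit_shrinkage_model(X, lam)
        my = fit_shrinkage_model(Y, lam)
        Xs = (X - mx.center) / mx.sdev
        Ys = (Y - my.center) / my.sdev
        return mx, my, Xs, Ys

    def test_full_shrinkage_kills_cross_block(self, rng):
        X, Y = rng.standard_normal((8, 12)), rng.standard_normal((8, 5))
        mx, my, Xs, Ys = self._models(X, Y, 1.0)
        np.testing.assert_allclose(compute_K_lowrank(mx, my, Xs, Ys), 0.0)

    def test_orthogonal_data_zero_K(self, rng):
        # project Y out of the span of centered X: zero empirical cross products
        n = 12
        X = rng.standard_normal((n, 4))
        Xc = X - X.mean(0)
        Y = rng.standard_normal((n, 3))
        Y = Y - Y.mean(0)
        Y = Y - Xc @ np.linalg.lstsq(Xc, Y, rcond=None)[0]
        Y = Y - Y.mean(0)
        assert np.allclose(Xc.T @ Y, 0.0, atol=1e-10)
        mx, my, Xs, Ys = self._models(X, Y, 0.5)
        np.testing.assert_allclose(compute_K_lowrank(mx, my, Xs, Ys), 0.0, atol=1e-12)

    def test_matches_dense_path(self, rng):
        X = rng.standard_normal((12, 30)) * rng.uniform(0.5, 2.0, 30)
        Y = rng.standard_normal((12, 8))
        lam = shrink_intensity(np.hstack([X, Y]))
        mx, my, Xs, Ys = self._models(X, Y, lam)
        got = compute_K_lowrank(mx, my, Xs, Ys)
        R = np.corrcoef(np.hstack([X, Y]), rowvar=False)
        Rs = lam * np.eye(38) + (1 - lam) * R
        dense = compute_K(Rs[:30, :30], Rs[:30, 30:], Rs[30:, 30:])
        np.testing.assert_allclose(got, dense, rtol=1e-8, atol=1e-10)

    def test_mismatched_intensities_rejected(self, rng):
        X, Y = rng.standard_normal((8, 6)), rng.standard_normal((8, 4))
        mx = fit_shrinkage_model(X, 0.3)
        my = fit_shrinkage_model(Y, 0.6)
        with pytest.raises(ValueError, match="intensit"):
            compute_K_lowrank(mx, my, X, Y)


class TestSvdSigned:
    def test_signed_diagonal_passthrough(self):
        K = np.diag([0.5, -0.3])
        Q_X, Q_Y, lam = svd_signed(K)
        np.testing.assert_allclose(Q_X, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(Q_Y, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(lam, [0.5, -0.3], atol=1e-12)

    def test_zero_matrix(self):
        Q_X, Q_Y, lam = svd_signed(np.zeros((3, 2)))
        np.testing.assert_allclose(lam, 0.0)
        np.testing.assert_allclose(Q_X @ Q_X.T, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(Q_Y @ Q_Y.T, np.eye(2), atol=1e-12)
        assert np.all(np.diagonal(Q_X) >= 0) and np.all(np.diagonal(Q_Y) >= 0)

    def test_reconstruction_and_flip_invariance(self, rng):
        K = rng.standard_normal((5, 4))
        Q_X, Q_Y, lam = svd_signed(K)
        np.testing.assert_allclose(Q_X.T @ np.diag(lam) @ Q_Y, K, atol=1e-10)
        assert np.all(np.diagonal(Q_X) >= 0) and np.all(np.diagonal(Q_Y) >= 0)
        np.testing.assert_allclose(
            np.abs(lam), np.linalg.svd(K, compute_uv=False), atol=1e-12
        )
        # simultaneous flip of row i of Q_X and sign of lambda_i is a no-op
        Q_Xf = Q_X.copy()
        Q_Xf[1] *= -1
        lamf = lam.copy()
        lamf[1] *= -1
        np.testing.assert_allclose(Q_Xf.T @ np.diag(lamf) @ Q_Y, K, atol=1e-10)

    def test_ordering_by_magnitude(self, rng):
        K = rng.standard_normal((6, 6)) * 0.1
        _, _, lam = svd_signed(K)
        assert np.all(np.diff(np.abs(lam)) <= 1e-14)


class TestCcaFit:
    def test_self_correlation(self, rng):
        X = rng.standard_normal((50, 4))
        model = cca_fit(X, X, estimator="empirical")
        np.testing.assert_allclose(model.lambdas, 1.0, atol=1e-8)

    def test_population_alternating_design(self):
        p, q, lam = 60, 10, 0.9
        Sigma_XY = np.zeros((p, q))
        truth = np.array([lam * (-1) ** i for i in range(q)])
        Sigma_XY[:q, :q] = np.diag(truth)
        model = cca_fit(
            estimator="population",
            moments=JointMoments(np.zeros(p), np.zeros(q), np.eye(p), np.eye(q),
                                 Sigma_XY),
        )
        assert model.m == q
        np.testing.assert_allclose(model.lambdas, truth, atol=1e-12)

    def test_empirical_matches_classical_eigen_oracle(self, rng):
        n, p, q = 200, 5, 4
        X = rng.standard_normal((n, p)) @ random_psd(rng, p)
        Y = 0.4 * X[:, :q] + rng.standard_normal((n, q))
        model = cca_fit(X, Y, estimator="empirical")
        oracle = classical_cca_eigen_oracle(X, Y)
        np.testing.assert_allclose(np.abs(model.lambdas), oracle, atol=1e-10)

    def test_model_invariants(self, rng):
        n, p, q = 120, 6, 4
        X = rng.standard_normal((n, p))
        Y = 0.5 * X[:, :q] + rng.standard_normal((n, q))
        model = cca_fit(X, Y, estimator="empirical")
        Z = np.hstack([X, Y])
        S = np.cov(Z, rowvar=False)
        Sx, Sy, Sxy = S[:p, :p], S[p:, p:], S[:p, p:]
        np.testing.assert_allclose(model.Q_X @ model.Q_X.T, np.eye(q), atol=1e-10)
        np.testing.assert_allclose(model.Q_Y @ model.Q_Y.T, np.eye(q), atol=1e-10)
        assert np.all(np.diagonal(model.Q_X) >= 0)
        assert np.all(np.diagonal(model.Q_Y) >= 0)
        np.testing.assert_allclose(model.W_X @ Sx @ model.W_X.T, np.eye(q),
                                   atol=1e-10)
        np.testing.assert_allclose(model.W_Y @ Sy @ model.W_Y.T, np.eye(q),
                                   atol=1e-10)
        np.testing.assert_allclose(model.W_X @ Sxy @ model.W_Y.T,
                                   np.diag(model.lambdas), atol=1e-10)
        # squared correlation-loadings per variable bounded by one
        assert np.all(np.diag(model.Psi_X.T @ model.Psi_X) <= 1 + 1e-10)
        np.testing.assert_allclose(np.diag(model.Psi_Y.T @ model.Psi_Y), 1.0,
                                   atol=1e-10)  # m = q: full rotation on Y side

    def test_empirical_needs_enough_samples(self, rng):
        X = rng.standard_normal((20, 60))
        Y = rng.standard_normal((20, 10))
        with pytest.raises(RankDeficiencyError, match="shrinkage"):
            cca_fit(X, Y, estimator="empirical")

    def test_determinism_byte_identical(self, rng):
        X = rng.standard_normal((30, 8))
        Y = rng.standard_normal((30, 5))
        a = cca_fit(X, Y, estimator="shrinkage")
        b = cca_fit(X, Y, estimator="shrinkage")
        assert np.array_equal(a.lambdas, b.lambdas)
        assert np.array_equal(a.W_X, b.W_X)
        assert np.array_equal(a.W_Y, b.W_Y)

    def test_scale_equivariance(self, rng):
        X = rng.standard_normal((100, 5))
        Y = 0.5 * X[:, :3] + rng.standard_normal((100, 3))
        c = np.array([2.0, 0.5, 3.0, 1.5, 10.0])
        a = cca_fit(X, Y, estimator="empirical")
        b = cca_fit(X * c, Y, estimator="empirical")
        np.testing.assert_allclose(a.lambdas, b.lambdas, atol=1e-10)
        np.testing.assert_allclose(b.W_X, a.W_X / c[None, :], rtol=1e-8)

    def test_standardize_flag_preserves_lambdas(self, rng):
        X = rng.standard_normal((80, 5)) * np.array([1, 10, 0.1, 5, 2.0])
        Y = 0.5 * X[:, :3] + rng.standard_normal((80, 3))
        a = cca_fit(X, Y, estimator="empirical")
        b = cca_fit(X, Y, estimator="empirical", standardize=True)
        np.testing.assert_allclose(a.lambdas, b.lambdas, atol=1e-10)

    def test_lowrank_and_dense_shrinkage_agree(self, rng):
        X = rng.standard_normal((40, 12))
        Y = rng.standard_normal((40, 5))
        a = cca_fit(X, Y, estimator="shrinkage", lowrank=True)
        b = cca_fit(X, Y, estimator="shrinkage", lowrank=False)
        np.testing.assert_allclose(a.lambdas, b.lambdas, atol=1e-8)
        np.testing.assert_allclose(a.W_X, b.W_X, atol=1e-8)


class TestScores:
    def test_translation_invariance(self, rng):
        X = rng.standard_normal((60, 4))
        Y = rng.standard_normal((60, 3))
        shift = rng.standard_normal(4)
        a = cca_fit(X, Y, estimator="empirical")
        b = cca_fit(X + shift, Y, estimator="empirical")
        sa, _ = scores(a, X, Y)
        sb, _ = scores(b, X + shift, Y)
        np.testing.assert_allclose(sa, sb, atol=1e-10)

    def test_in_sample_correlation_identity(self, rng):
        n, p, q = 300, 4, 3
        X = rng.standard_normal((n, p))
        Y = 0.6 * X[:, :q] + rng.standard_normal((n, q))
        model = cca_fit(X, Y, estimator="empirical")
        sx, sy = scores(model, X, Y)
        C = np.corrcoef(np.hstack([sx, sy]), rowvar=False)[:q, q:]
        np.testing.assert_allclose(np.diag(C), model.lambdas, atol=1e-8)
        np.testing.assert_allclose(C - np.diag(np.diag(C)), 0.0, atol=1e-8)

    def test_prewhitened_input_scores_are_centered_data(self, rng):
        # X already white and uncorrelated with itself only via identity W
        n = 2000
        Z = rng.standard_normal((n, 3))
        model = cca_fit(Z, Z.copy(), estimator="empirical")
        sx, _ = scores(model, Z, Z)
        # perfect self-correlation: scores are a rotation of the centered data
        np.testing.assert_allclose(
            np.cov(sx, rowvar=False), np.eye(3), atol=1e-10
        )


class TestRegressionView:
    def test_delta_examples(self):
        assert delta_mse([0.6, -0.8]) == pytest.approx(1.0)
        assert delta_mse(np.zeros(4)) == 0.0

    def test_delta_frobenius_identity(self, rng):
        K = rng.standard_normal((5, 3)) * 0.4
        _, _, lam = svd_signed(K)
        assert delta_mse(lam) == pytest.approx(np.sum(K**2), abs=1e-10)

    def test_no_predictor_case(self, rng):
        Sy = random_psd(rng, 2)
        m = JointMoments(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0]),
                         random_psd(rng, 3), Sy, np.zeros((3, 2)))
        reg = optimal_linear_predictor(m)
        np.testing.assert_allclose(reg.b, 0.0)
        np.testing.assert_allclose(reg.a, m.mu_Y)
        assert reg.delta == 0.0
        assert reg.mse_all == pytest.approx(np.trace(Sy))

    def test_whitened_inputs_reduce_to_cross_correlation(self, rng):
        P = rng.uniform(-0.4, 0.4, (3, 2))
        m = JointMoments(np.zeros(3), np.zeros(2), np.eye(3), np.eye(2), P)
        reg = optimal_linear_predictor(m)
        np.testing.assert_allclose(reg.b, P, atol=1e-12)

    def test_numeric_optimality(self, rng):
        Sx = random_psd(rng, 3)
        Sy = random_psd(rng, 2)
        B = rng.uniform(-0.3, 0.3, (3, 2))
        Sxy = Sx @ B  # guarantees a PSD-compatible cross block for small B
        mu_X, mu_Y = rng.standard_normal(3), rng.standard_normal(2)
        m = JointMoments(mu_X, mu_Y, Sx, Sy, Sxy)

        def mse(a, b):
            bias = mu_Y - (a + b.T @ mu_X)
            return float(bias @ bias + np.trace(Sy + b.T @ Sx @ b - 2 * b.T @ Sxy))

        reg = optimal_linear_predictor(m)
        best = mse(reg.a, reg.b)
        assert best == pytest.approx(reg.mse_all, abs=1e-10)
        for _ in range(100):
            da = rng.standard_normal(2) * 0.1
            db = rng.standard_normal((3, 2)) * 0.1
            assert mse(reg.a + da, reg.b + db) >= best - 1e-12

    def test_cca_whitened_regression_coefficients_are_lambdas(self, rng):
        n, p, q = 400, 4, 3
        X = rng.standard_normal((n, p))
        Y = 0.6 * X[:, :q] + rng.standard_normal((n, q))
        model = cca_fit(X, Y, estimator="empirical")
        sx, sy = scores(model, X, Y)
        Z = np.hstack([sx, sy])
        S = np.cov(Z, rowvar=False)
        m = JointMoments(sx.mean(0), sy.mean(0), S[:q, :q], S[q:, q:], S[:q, q:])
        reg = optimal_linear_predictor(m)
        np.testing.assert_allclose(reg.b, np.diag(model.lambdas), atol=1e-8)
        assert reg.delta == pytest.approx(delta_mse(model.lambdas), abs=1e-8)
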