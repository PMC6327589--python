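"""Canonical correlation analysis as a uniquely determined whitening transform.

CCA of two random vectors X (dim p) and Y (dim q) is the simultaneous
whitening of both vectors under the constraint that the cross-correlation of
the whitened vectors is diagonal.  The whole analysis reduces to the SVD of
the correlation-adjusted cross-correlation matrix

    K = P_X^{-1/2} P_XY P_Y^{-1/2} = Q_X^T  Lambda  Q_Y,

whose singular values are the magnitudes of the m = min(p, q) canonical
correlations and whose (semi-orthogonal) singular-vector matrices Q_X, Q_Y
are the CCA rotations.  The residual per-component sign ambiguity of the SVD
is resolved by requiring both rotations to have a nonnegative diagonal (the
minimal rotation, closest to the identity) and moving the signs into the
canonical correlations lambda_i, which are therefore *signed*: they are the
regression coefficients linking the CCA-whitened variables, and a negative
lambda_i denotes an inverse association between the paired canonical
variates.  The canonical directions are the rows of the whitening matrices
W_X = Q_X P_X^{-1/2} V_X^{-1/2} and W_Y likewise.

Estimation backends: empirical moments (classical, requires n > max(p, q)),
shrinkage of the joint correlation matrix (n << p workable, with a low-rank
path that never forms a p x p matrix), or exact population moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shrinkage import (
    ShrinkageCorrelationModel,
    _standardize,
    fit_shrinkage_model,
    inv_sqrt_mult,
    pow_mult,
    shrink_intensity,
)
from .whitening import (
    JointMoments,
    RankDeficiencyError,
    decompose_covariance,
    matrix_power_psd,
)


@dataclass
class CCAModel:
    """Fitted CCA: rotations, signed correlations, directions, loadings.

    The m rows of ``W_X`` / ``W_Y`` are the canonical directions alpha_i /
    beta_i; ``lambdas`` holds the signed canonical correlations ordered by
    decreasing magnitude.  ``scale_X`` / ``scale_Y`` record the column
    scaling applied before fitting (ones unless ``standardize=True``).
    """

    m: int
    lambdas: np.ndarray
    Q_X: np.ndarray
    Q_Y: np.ndarray
    W_X: np.ndarray
    W_Y: np.ndarray
    Phi_X: np.ndarray
    Phi_Y: np.ndarray
    Psi_X: np.ndarray
    Psi_Y: np.ndarray
    mu_X: np.ndarray
    mu_Y: np.ndarray
    estimator_meta: dict = field(default_factory=dict)
    scale_X: np.ndarray | None = None
    scale_Y: np.ndarray | None = None


@dataclass
class RegressionSummary:
    """Best linear predictor of Y from X and its predictive-MSE accounting.

    ``delta = mse_zero - mse_all`` is the decrease in predictive mean squared
    error gained by including the predictors; it is always nonnegative.
    """

    a: np.ndarray
    b: np.ndarray
    delta: float
    mse_zero: float
    mse_all: float


def compute_K(
    P_X: np.ndarray, P_XY: np.ndarray, P_Y: np.ndarray, *, strict: bool = False
) -> np.ndarray:
    """Correlation-adjusted cross-correlation K = P_X^{-1/2} P_XY P_Y^{-1/2}.

    All singular values of K lie in [0, 1] (up to round-off) when the joint
    correlation matrix is PSD.
    """
    P_XY = np.atleast_2d(np.asarray(P_XY, dtype=float))
    PX_m12 = matrix_power_psd(P_X, -0.5, strict=strict)
    PY_m12 = matrix_power_psd(P_Y, -0.5, strict=strict)
    return PX_m12 @ P_XY @ PY_m12


def compute_K_lowrank(
    model_X: ShrinkageCorrelationModel,
    model_Y: ShrinkageCorrelationModel,
    Xs: np.ndarray,
    Ys: np.ndarray,
) -> np.ndarray:
    """K from shrinkage models without materializing p x p or q x q matrices.

    The shrunk cross-correlation block is (1-lambda) R_hat_XY =
    (1-lambda)/(n-1) Xs^T Ys for standardized data Xs, Ys; it is wrapped by
    R_X^{-1/2} on the left and R_Y^{-1/2} on the right via the low-rank
    multiply.  Both models must share the joint shrinkage intensity.
    """
    if abs(model_X.lambda_shrink - model_Y.lambda_shrink) > 1e-12:
        raise ValueError(
            "models have different shrinkage intensities "
            f"({model_X.lambda_shrink} vs {model_Y.lambda_shrink}); fit both "
            "from the joint intensity"
        )
    Xs = np.asarray(Xs, dtype=float)
    Ys = np.asarray(Ys, dtype=float)
    n = Xs.shape[0]
    if Ys.shape[0] != n:
        raise ValueError("Xs and Ys must have the same number of rows")
    lam = model_X.lambda_shrink
    cross = (1.0 - lam) / (n - 1.0) * (Xs.T @ Ys)  # p x q
    K = inv_sqrt_mult(model_X, cross)
    return inv_sqrt_mult(model_Y, K.T).T


def svd_signed(K: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of K with the positive-diagonal sign convention.

    Returns ``(Q_X, Q_Y, lambdas)`` with ``K = Q_X^T diag(lambdas) Q_Y``,
    both rotations row-semi-orthogonal with nonnegative diagonal entries
    (zero counts as positive: no flip), and ``|lambdas|`` equal to the
    singular values of K in descending order.  Row i of Q_X is scaled by
    s_i = sign((Q_X)_ii), row i of Q_Y by t_i = sign((Q_Y)_ii), and
    lambda_i = s_i t_i d_i, which leaves the product Q_X^T diag(lambda) Q_Y
    invariant.  For exactly tied singular values the decomposition is not
    unique; the ordering of tied components follows the underlying SVD.
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    u, d, vh = np.linalg.svd(K, full_matrices=False)
    Q_X = u.T  # m x p
    Q_Y = vh  # m x q
    # diagonal entries within round-off of zero count as positive (no flip)
    s = np.where(np.diagonal(Q_X) < -1e-12, -1.0, 1.0)
    t = np.where(np.diagonal(Q_Y) < -1e-12, -1.0, 1.0)
    Q_X = s[:, None] * Q_X
    Q_Y = t[:, None] * Q_Y
    lambdas = s * t * d
    return Q_X, Q_Y, lambdas


def delta_mse(lambdas: np.ndarray) -> float:
    """Predictive-MSE reduction Delta = sum_i lambda_i^2.

    For CCA-whitened variables the regression coefficients are exactly the
    signed canonical correlations, so each lambda_i^2 is the variable
    importance of canonical component i and their sum is the total decrease
    in predictive MSE; it also equals Tr(K^T K).
    """
    lambdas = np.asarray(lambdas, dtype=float)
    return float(np.sum(lambdas**2))


def optimal_linear_predictor(moments: JointMoments) -> RegressionSummary:
    """Best linear predictor Y* = a + b^T X under the given joint moments.

    b = Sigma_X^{-1} Sigma_XY, a = mu_Y - b^T mu_X;
    Delta = Tr(Sigma_YX Sigma_X^{-1} Sigma_XY) is the decrease in predictive
    MSE relative to the predictor-free model (whose MSE is Tr(Sigma_Y)).
    """
    try:
        b = np.linalg.solve(moments.Sigma_X, moments.Sigma_XY)
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError(f"Sigma_X is singular: {exc}") from exc
    a = moments.mu_Y - b.T @ moments.mu_X
    mse_zero = float(np.trace(moments.Sigma_Y))
    delta = float(np.trace(moments.Sigma_XY.T @ b))
    return RegressionSummary(
        a=a, b=b, delta=delta, mse_zero=mse_zero, mse_all=mse_zero - delta
    )


def _fit_from_dense(
    V_X: np.ndarray,
    P_X: np.ndarray,
    V_Y: np.ndarray,
    P_Y: np.ndarray,
    P_XY: np.ndarray,
    mu_X: np.ndarray,
    mu_Y: np.ndarray,
    meta: dict,
    *,
    strict: bool = False,
) -> CCAModel:
    """Assemble a CCAModel from dense variance/correlation blocks."""
    K = compute_K(P_X, P_XY, P_Y, strict=strict)
    Q_X, Q_Y, lambdas = svd_signed(K)
    PX_m12 = matrix_power_psd(P_X, -0.5, strict=strict)
    PY_m12 = matrix_power_psd(P_Y, -0.5, strict=strict)
    PX_12 = matrix_power_psd(P_X, +0.5)
    PY_12 = matrix_power_psd(P_Y, +0.5)
    sx, sy = np.sqrt(V_X), np.sqrt(V_Y)
    return CCAModel(
        m=lambdas.size,
        lambdas=lambdas,
        Q_X=Q_X,
        Q_Y=Q_Y,
        W_X=(Q_X @ PX_m12) / sx[None, :],
        W_Y=(Q_Y @ PY_m12) / sy[None, :],
        Phi_X=(Q_X @ PX_12) * sx[None, :],
        Phi_Y=(Q_Y @ PY_12) * sy[None, :],
        Psi_X=Q_X @ PX_12,
        Psi_Y=Q_Y @ PY_12,
        mu_X=mu_X,
        mu_Y=mu_Y,
        estimator_meta=meta,
    )


def cca_fit(
    X: np.ndarray | None = None,
    Y: np.ndarray | None = None,
    estimator: str = "empirical",
    *,
    moments: JointMoments | None = None,
    standardize: bool = False,
    lambda_shrink: float | str = "auto",
    lowrank: bool | None = None,
    min_intensity: float | None = None,
) -> CCAModel:
    """Fit the CCA whitening model.

    Parameters
    ----------
    X, Y
        Data matrices with matched rows (required for data estimators).
    estimator
        ``"empirical"`` (classical, needs n > max(p, q)), ``"shrinkage"``
        (joint shrinkage of the correlation matrix; a low-rank path is used
        automatically when n <= max(p, q)), or ``"population"`` with exact
        ``moments`` supplied.
    standardize
        Z-score columns before fitting.  Canonical correlations are
        invariant under this; directions are reported in standardized units.
    lambda_shrink
        ``"auto"`` (analytic intensity from the column-concatenated [X | Y]
        matrix) or an explicit value in (0, 1].
    lowrank
        Force (True) or forbid (False) the low-rank shrinkage path; default
        selects it when n <= max(p, q).
    """
    if estimator == "population":
        if moments is None:
            raise ValueError("population mode requires moments=JointMoments(...)")
        dx = decompose_covariance(moments.Sigma_X)
        dy = decompose_covariance(moments.Sigma_Y)
        P_XY = moments.Sigma_XY / np.outer(np.sqrt(dx.V), np.sqrt(dy.V))
        return _fit_from_dense(
            dx.V, dx.P, dy.V, dy.P, P_XY, moments.mu_X, moments.mu_Y,
            {"estimator": "population"},
        )

    if X is None or Y is None:
        raise ValueError("data estimators require X and Y")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows (samples)")
    n, p = X.shape
    q = Y.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")

    mu_X, mu_Y = X.mean(axis=0), Y.mean(axis=0)
    scale_X = scale_Y = None
    if standardize:
        scale_X = X.std(axis=0, ddof=1)
        scale_Y = Y.std(axis=0, ddof=1)
        X = (X - mu_X) / scale_X
        Y = (Y - mu_Y) / scale_Y
        mu_X_fit, mu_Y_fit = np.zeros(p), np.zeros(q)
    else:
        mu_X_fit, mu_Y_fit = mu_X, mu_Y

    if estimator == "empirical":
        if n <= max(p, q):
            raise RankDeficiencyError(
                f"empirical estimator needs n > max(p, q) = {max(p, q)}, got "
                f"n = {n}; use estimator='shrinkage'"
            )
        joint = np.hstack([X, Y])
        R = np.corrcoef(joint, rowvar=False)
        V = joint.var(axis=0, ddof=1)
        model = _fit_from_dense(
            V[:p], R[:p, :p], V[p:], R[p:, p:], R[:p, p:],
            mu_X_fit, mu_Y_fit, {"estimator": "empirical"}, strict=True,
        )
    elif estimator == "shrinkage":
        joint = np.hstack([X, Y])
        if lambda_shrink == "auto":
            lam = shrink_intensity(joint, min_intensity=min_intensity)
        else:
            lam = float(lambda_shrink)
        use_lowrank = lowrank if lowrank is not None else (n <= max(p, q))
        meta = {"estimator": "shrinkage", "lambda_shrink": lam,
                "lowrank": use_lowrank}
        if use_lowrank:
            model_X = fit_shrinkage_model(X, lam)
            model_Y = fit_shrinkage_model(Y, lam)
            Xs = (X - model_X.center) / model_X.sdev
            Ys = (Y - model_Y.center) / model_Y.sdev
            K = compute_K_lowrank(model_X, model_Y, Xs, Ys)
            Q_X, Q_Y, lambdas = svd_signed(K)
            sx, sy = model_X.sdev, model_Y.sdev
            W_X = inv_sqrt_mult(model_X, Q_X.T).T / sx[None, :]
            W_Y = inv_sqrt_mult(model_Y, Q_Y.T).T / sy[None, :]
            Psi_X = pow_mult(model_X, Q_X.T, +0.5).T
            Psi_Y = pow_mult(model_Y, Q_Y.T, +0.5).T
            model = CCAModel(
                m=lambdas.size, lambdas=lambdas, Q_X=Q_X, Q_Y=Q_Y,
                W_X=W_X, W_Y=W_Y,
                Phi_X=Psi_X * sx[None, :], Phi_Y=Psi_Y * sy[None, :],
                Psi_X=Psi_X, Psi_Y=Psi_Y,
                mu_X=mu_X_fit, mu_Y=mu_Y_fit, estimator_meta=meta,
            )
        else:
            R = np.corrcoef(joint, rowvar=False)
            Rs = lam * np.eye(p + q) + (1.0 - lam) * R
            V = joint.var(axis=0, ddof=1)
            model = _fit_from_dense(
                V[:p], Rs[:p, :p], V[p:], Rs[p:, p:], Rs[:p, p:],
                mu_X_fit, mu_Y_fit, meta,
            )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    model.mu_X, model.mu_Y = mu_X, mu_Y
    model.scale_X, model.scale_Y = scale_X, scale_Y
    return model


def scores(
    model: CCAModel, X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical scores (variates): project centered data on the directions.

    Row i of the outputs is (W_X (x_i - mu_X), W_Y (y_i - mu_Y)) (with the
    fitted column scaling applied first if the model was standardized).
    Under empirical full-rank fitting, the in-sample correlation of paired
    score columns equals the signed canonical correlation lambda_i and
    non-paired columns are uncorrelated.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != model.W_X.shape[1] or Y.shape[1] != model.W_Y.shape[1]:
        raise ValueError("data dimensions do not match the fitted model")
    Xc = X - model.mu_X
    Yc = Y - model.mu_Y
    if model.scale_X is not None:
        Xc = Xc / model.scale_X
    if model.scale_Y is not None:
        Yc = Yc / model.scale_Y
    return Xc @ model.W_X.T, Yc @ model.W_Y.T
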