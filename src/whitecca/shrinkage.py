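"""Shrinkage estimation of correlation matrices with low-rank fast algebra.

For n samples of p variables with n << p the empirical correlation matrix
R_hat is singular and a poor estimate.  The analytic shrinkage estimator
pulls it toward the identity,

    R* = lambda * I + (1 - lambda) * R_hat,

with the variance-minimizing intensity estimated from the data (the
Schafer-Strimmer analytic formula for the identity target):

    lambda* = sum_{i != j} var_hat(r_ij) / sum_{i != j} r_ij^2,

clipped to [0, 1].  Because R_hat has rank r <= min(n - 1, p), R* can be
held in the low-rank form

    R* = lambda * (I_p + U N U^T)

with U (p x r, orthonormal columns) from the thin SVD of the standardized
data and N a positive r x r diagonal.  This representation supports
O(p r d) computation of R*^{-1/2} M (and other symmetric powers) without
ever materializing a p x p matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .whitening import DegenerateVariableError


class InsufficientSamplesError(ValueError):
    """Fewer samples than the minimum (n >= 3) needed for intensity estimation."""


@dataclass
class ShrinkageCorrelationModel:
    """Low-rank representation R = lambda * (I + U N U^T) of a shrunk correlation.

    Attributes
    ----------
    lambda_shrink : shrinkage intensity in (0, 1].
    U : (p, r) matrix with orthonormal columns (right singular vectors of
        the standardized data).
    N : length-r vector, the positive diagonal of N.
    sdev : length-p empirical standard deviations (ddof=1).
    center : length-p empirical column means.
    n : number of samples the model was fitted on.
    """

    lambda_shrink: float
    U: np.ndarray
    N: np.ndarray
    sdev: np.ndarray
    center: np.ndarray
    n: int

    @property
    def p(self) -> int:
        return self.U.shape[0]

    @property
    def rank(self) -> int:
        return self.U.shape[1]

    def dense_correlation(self) -> np.ndarray:
        """Materialize R = lambda (I + U N U^T).  For small p / testing only."""
        lam = self.lambda_shrink
        return lam * (np.eye(self.p) + (self.U * self.N[None, :]) @ self.U.T)


def _standardize(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center columns and scale by ddof=1 standard deviation."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, p = data.shape
    if n < 3:
        raise InsufficientSamplesError(f"need at least 3 samples, got {n}")
    center = data.mean(axis=0)
    sdev = data.std(axis=0, ddof=1)
    bad = np.flatnonzero(sdev == 0)
    if bad.size:
        raise DegenerateVariableError(
            f"column {int(bad[0])} has zero variance"
        )
    return (data - center) / sdev, center, sdev


def shrink_intensity(data: np.ndarray, *, min_intensity: float | None = None) -> float:
    """Analytic variance-minimizing shrinkage intensity toward the identity.

    With xs the ddof=1-standardized data and w_kij = xs_ki * xs_kj, the
    empirical correlations are r_ij = n/(n-1) * mean_k(w_kij) and their
    estimated variances var_hat(r_ij) = n/(n-1)^3 * sum_k (w_kij - wbar_ij)^2;
    the intensity is the ratio of the summed variances to the summed squared
    off-diagonal correlations, clipped into [0, 1].  A zero denominator
    (all off-diagonal correlations exactly zero) yields full shrinkage, 1.

    Parameters
    ----------
    data : (n, p) matrix, n >= 3, no constant column.
    min_intensity : optional floor applied when the estimate is exactly 0,
        guaranteeing a strictly positive-definite estimate.
    """
    xs, _, _ = _standardize(data)
    n = xs.shape[0]
    # sum_k w_kij = xs^T xs; sum_k w_kij^2 = (xs^2)^T (xs^2)
    sw = xs.T @ xs
    sw2 = (xs**2).T @ (xs**2)
    wbar = sw / n
    r = (n / (n - 1.0)) * wbar
    # sum_k (w - wbar)^2 = sum w^2 - n wbar^2
    var_r = (n / (n - 1.0) ** 3) * (sw2 - n * wbar**2)
    off = ~np.eye(xs.shape[1], dtype=bool)
    denom = float(np.sum(r[off] ** 2))
    numer = float(np.sum(var_r[off]))
    if denom == 0.0:
        lam = 1.0
    else:
        lam = min(1.0, max(0.0, numer / denom))
    if lam == 0.0 and min_intensity is not None:
        lam = float(min_intensity)
    return lam


def fit_shrinkage_model(
    data: np.ndarray,
    lambda_shrink: float | str = "auto",
    *,
    min_intensity: float | None = None,
    svd_rtol: float = 1e-12,
) -> ShrinkageCorrelationModel:
    """Fit the low-rank shrinkage correlation model to data.

    The standardized data matrix xs (n x p) is factored by thin SVD,
    xs = L diag(d) U^T; then R_hat = U diag(d^2/(n-1)) U^T and

        R* = lambda I + (1-lambda) R_hat = lambda (I + U N U^T),
        N_k = (1-lambda)/lambda * d_k^2 / (n-1).

    Singular values below ``svd_rtol * d_1`` are dropped (rank truncation).

    Raises
    ------
    ValueError
        If ``lambda_shrink`` is 0: the identity part of the representation
        vanishes and (for rank < p) the estimate is singular; use the
        empirical estimator instead.
    """
    xs, center, sdev = _standardize(data)
    n, p = xs.shape
    if lambda_shrink == "auto":
        lam = shrink_intensity(data, min_intensity=min_intensity)
    else:
        lam = float(lambda_shrink)
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"shrinkage intensity must be in [0, 1], got {lam}")
    _, d, Uh = np.linalg.svd(xs, full_matrices=False)
    if d.size and d[0] > 0:
        keep = d >= svd_rtol * d[0]
    else:
        keep = np.zeros_like(d, dtype=bool)
    d = d[keep]
    U = Uh[keep].T  # p x r, orthonormal columns
    if lam == 0.0:
        raise ValueError(
            "shrinkage intensity 0 leaves a singular low-rank estimate "
            f"(rank {d.size} < p={p}); use the empirical estimator or a "
            "positive intensity"
        )
    if lam == 1.0:
        N = np.zeros_like(d)
    else:
        N = (1.0 - lam) / lam * d**2 / (n - 1.0)
    return ShrinkageCorrelationModel(
        lambda_shrink=lam, U=U, N=N, sdev=sdev, center=center, n=n
    )


def pow_mult(
    model: ShrinkageCorrelationModel, M: np.ndarray, exponent: float
) -> np.ndarray:
    """Compute R^exponent @ M without materializing R (p x p).

    Uses R^e = lambda^e (I + U ((I+N)^e - I) U^T), valid for U with
    orthonormal columns.  Peak intermediates are p x r and r x d.
    """
    M = np.asarray(M, dtype=float)
    squeeze = M.ndim == 1
    if squeeze:
        M = M[:, None]
    if M.shape[0] != model.p:
        raise ValueError(f"M has {M.shape[0]} rows, model expects {model.p}")
    lam = model.lambda_shrink
    f = (1.0 + model.N) ** exponent - 1.0
    out = lam**exponent * (M + model.U @ (f[:, None] * (model.U.T @ M)))
    return out[:, 0] if squeeze else out


def inv_sqrt_mult(model: ShrinkageCorrelationModel, M: np.ndarray) -> np.ndarray:
    """Compute R^{-1/2} @ M via the low-rank identity.

    Equals lambda^{-1/2} (M - U (I - (I+N)^{-1/2}) (U^T M)); never allocates
    a p x p intermediate.
    """
    return pow_mult(model, M, -0.5)
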