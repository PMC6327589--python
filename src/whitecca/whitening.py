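"""Whitening (sphering) transformations.

A whitening transform maps a random vector :math:`X` with covariance
:math:`\\Sigma` to :math:`\\tilde X = W X` with :math:`\\mathrm{var}(\\tilde X)
= I`.  The constraint :math:`W \\Sigma W^T = I` leaves a rotational freedom:
every whitening matrix can be written

.. math::

    W = Q\\, P^{-1/2}\\, V^{-1/2},

where :math:`\\Sigma = V^{1/2} P V^{1/2}` splits the covariance into variances
``V`` (diagonal) and correlations ``P``, and ``Q`` is an orthogonal (or, for
reduced transforms, row-semi-orthogonal) rotation.  The choice of ``Q``
selects the member of the whitening family: ``Q = I`` gives ZCA-cor
(correlation-based Mahalanobis) whitening, ``Q = G^T`` from the spectral
decomposition ``P = G \\Theta G^T`` gives PCA-cor whitening.  The inverse
(coloring) transform is governed by the mixing matrix
:math:`\\Phi = Q P^{1/2} V^{1/2}` with :math:`X = \\Phi^T \\tilde X`, and the
correlation-loadings :math:`\\Psi = Q P^{1/2}` are the correlations between
whitened components and the original variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateVariableError(ValueError):
    """A variable has zero (or negative) variance and cannot be standardized."""


class RankDeficiencyError(ValueError):
    """A correlation/covariance matrix is (numerically) singular.

    For n smaller than the dimension this is expected; shrinkage estimation
    (see :mod:`whitecca.shrinkage`) regularizes the estimate and avoids it.
    """


class RotationContractError(ValueError):
    """A user-supplied rotation matrix does not have orthonormal rows."""


@dataclass
class JointMoments:
    """First and second moments of a composite random vector (X^T, Y^T)^T.

    Parameters
    ----------
    mu_X, mu_Y
        Mean vectors of length p and q.
    Sigma_X, Sigma_Y
        Within-set covariance matrices (p x p, q x q), symmetric PSD.
    Sigma_XY
        Cross-covariance cov(X, Y), p x q.
    """

    mu_X: np.ndarray
    mu_Y: np.ndarray
    Sigma_X: np.ndarray
    Sigma_Y: np.ndarray
    Sigma_XY: np.ndarray

    def __post_init__(self) -> None:
        self.mu_X = np.atleast_1d(np.asarray(self.mu_X, dtype=float))
        self.mu_Y = np.atleast_1d(np.asarray(self.mu_Y, dtype=float))
        self.Sigma_X = np.atleast_2d(np.asarray(self.Sigma_X, dtype=float))
        self.Sigma_Y = np.atleast_2d(np.asarray(self.Sigma_Y, dtype=float))
        self.Sigma_XY = np.atleast_2d(np.asarray(self.Sigma_XY, dtype=float))
        p, q = self.mu_X.size, self.mu_Y.size
        if self.Sigma_X.shape != (p, p) or self.Sigma_Y.shape != (q, q):
            raise ValueError("covariance block shapes do not match mean lengths")
        if self.Sigma_XY.shape != (p, q):
            raise ValueError(f"Sigma_XY must be {p}x{q}, got {self.Sigma_XY.shape}")
        for name, S in (("Sigma_X", self.Sigma_X), ("Sigma_Y", self.Sigma_Y)):
            if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
                raise ValueError(f"{name} is not symmetric")
            if np.any(np.diag(S) <= 0):
                idx = int(np.flatnonzero(np.diag(S) <= 0)[0])
                raise DegenerateVariableError(
                    f"{name} has non-positive variance at index {idx}"
                )

    @property
    def p(self) -> int:
        return self.mu_X.size

    @property
    def q(self) -> int:
        return self.mu_Y.size

    def joint_covariance(self) -> np.ndarray:
        """Assemble the (p+q) x (p+q) block covariance matrix."""
        return np.block([[self.Sigma_X, self.Sigma_XY],
                         [self.Sigma_XY.T, self.Sigma_Y]])

    def check_psd(self, tol: float = 1e-8) -> None:
        """Raise if the composite covariance is not PSD within tolerance."""
        w = np.linalg.eigvalsh(self.joint_covariance())
        if w.min() < -tol * max(1.0, w.max()):
            raise ValueError(
                f"composite covariance is not PSD: min eigenvalue {w.min():.3e}"
            )


@dataclass
class CorVarDecomposition:
    """Variance/correlation split of a covariance: Sigma = V^{1/2} P V^{1/2}.

    ``V`` is stored as the 1-d vector of variances; ``P`` has unit diagonal.
    """

    V: np.ndarray
    P: np.ndarray


@dataclass
class WhiteningTransform:
    """A sphering solution W = Q P^{-1/2} V^{-1/2} with its derived matrices.

    Attributes
    ----------
    Q : (k, p) rotation with orthonormal rows.
    W : (k, p) whitening matrix, W Sigma W^T = I_k.
    Phi : (k, p) mixing (coloring) matrix; for k = p, Phi^T = W^{-1}.
    Psi : (k, p) correlation-loadings, cor(whitened, original).
    center : optional length-p vector subtracted before whitening.
    """

    Q: np.ndarray
    W: np.ndarray
    Phi: np.ndarray
    Psi: np.ndarray
    center: np.ndarray | None = None


def decompose_covariance(Sigma: np.ndarray) -> CorVarDecomposition:
    """Split a covariance matrix into variances and a correlation matrix.

    Returns ``CorVarDecomposition(V, P)`` with ``Sigma = diag(V)^{1/2} P
    diag(V)^{1/2}`` and ``diag(P) == 1`` exactly.

    Raises
    ------
    DegenerateVariableError
        If any diagonal entry of ``Sigma`` is not strictly positive.
    """
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    v = np.diag(Sigma).copy()
    bad = np.flatnonzero(v <= 0)
    if bad.size:
        raise DegenerateVariableError(
            f"variable {int(bad[0])} has non-positive variance {v[bad[0]]:g}"
        )
    s = np.sqrt(v)
    P = Sigma / np.outer(s, s)
    np.fill_diagonal(P, 1.0)
    return CorVarDecomposition(V=v, P=P)


def matrix_power_psd(
    P: np.ndarray,
    exponent: float,
    *,
    strict: bool = False,
    floor: float = 1e-10,
) -> np.ndarray:
    """Symmetric matrix power of a PSD matrix via eigendecomposition.

    Supports the half-integer powers needed for whitening (+1/2, -1/2); any
    real exponent works for strictly positive definite input.  Eigenvalues
    below ``floor * max(eigenvalue)`` are clamped to that floor for negative
    exponents (lenient mode) or raise :class:`RankDeficiencyError` in strict
    mode.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    w, G = np.linalg.eigh((P + P.T) / 2.0)
    wmax = max(w.max(), 0.0)
    cutoff = floor * wmax if wmax > 0 else floor
    if exponent < 0:
        if strict and w.min() < cutoff:
            raise RankDeficiencyError(
                "matrix is numerically rank deficient (min eigenvalue "
                f"{w.min():.3e} < {cutoff:.3e}); consider shrinkage estimation"
            )
        w = np.maximum(w, cutoff)
    else:
        w = np.maximum(w, 0.0)
    return (G * w**exponent) @ G.T


def _pca_cor_rotation(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA-cor rotation Q = G^T from P = G Theta G^T, eigenvalues descending.

    Ties are broken by original index (stable sort); row signs of Q are
    flipped so the diagonal of Q is nonnegative (zero entries count as
    positive, i.e. no flip): orthogonal matrices with positive diagonal are
    the minimal rotations, closest to the identity.
    """
    w, G = np.linalg.eigh((P + P.T) / 2.0)
    order = np.argsort(-w, kind="stable")
    w = w[order]
    Q = G[:, order].T
    signs = np.where(np.diag(Q) < 0, -1.0, 1.0)
    return signs[:, None] * Q, w


def make_whitening(
    Sigma: np.ndarray,
    rotation: str | np.ndarray = "zca_cor",
    *,
    center: np.ndarray | None = None,
    strict: bool = False,
) -> WhiteningTransform:
    """Construct a whitening transform for covariance ``Sigma``.

    Parameters
    ----------
    Sigma
        Symmetric PSD covariance matrix (p x p) with positive diagonal.
    rotation
        ``"zca_cor"`` (Q = I), ``"pca_cor"`` (Q from the spectral
        decomposition of the correlation matrix, eigenvalues descending,
        rows sign-fixed to a nonnegative diagonal), or an explicit (k, p)
        matrix with orthonormal rows.
    center
        Optional location parameter stored on the transform; whitening of
        data is applied to ``data - center``.
    strict
        Raise on numerically singular correlation instead of flooring
        eigenvalues.
    """
    dec = decompose_covariance(Sigma)
    P, v = dec.P, dec.V
    p = v.size
    if isinstance(rotation, str):
        if rotation == "zca_cor":
            Q = np.eye(p)
        elif rotation == "pca_cor":
            Q, _ = _pca_cor_rotation(P)
        else:
            raise ValueError(f"unknown rotation {rotation!r}")
    else:
        Q = np.atleast_2d(np.asarray(rotation, dtype=float))
        if Q.shape[1] != p:
            raise RotationContractError(
                f"rotation has {Q.shape[1]} columns, expected {p}"
            )
        if not np.allclose(Q @ Q.T, np.eye(Q.shape[0]), atol=1e-8):
            raise RotationContractError("rotation rows are not orthonormal")
    P_m12 = matrix_power_psd(P, -0.5, strict=strict)
    P_12 = matrix_power_psd(P, +0.5)
    s = np.sqrt(v)
    W = (Q @ P_m12) / s[None, :]
    Phi = (Q @ P_12) * s[None, :]
    Psi = Q @ P_12
    return WhiteningTransform(Q=Q, W=W, Phi=Phi, Psi=Psi, center=center)


def apply_transform(
    transform: WhiteningTransform,
    data: np.ndarray,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Whiten data rows: row_i -> W (row_i - center).

    ``center`` defaults to the transform's stored center, then to zero.
    Whitening is location-equivariant, so centering by the (possibly
    shifted) mean yields identical output for translated data.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    p = transform.W.shape[1]
    if data.shape[1] != p:
        raise ValueError(f"data has {data.shape[1]} columns, transform expects {p}")
    if center is None:
        center = transform.center
    if center is not None:
        data = data - np.asarray(center, dtype=float)[None, :]
    return data @ transform.W.T
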