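"""Two-layer latent-variable generative model for CCA, and simulation studies.

Level 1 holds mutually uncorrelated latent variables Z^X (dim p), Z^Y
(dim q) and Z^shared (dim m = min(p, q)), each with mean 0 and variance 1 but
otherwise of free distribution (Gaussian by default; a rescaled t gives a
heavy-tailed, robustness-oriented variant).  Level 2 mixes shared and
non-shared latents into the CCA-whitened variables

    Xtilde_i = sqrt(1 - |lambda_i|) Z^X_i + sqrt(|lambda_i|) Z^shared_i
    Ytilde_i = sqrt(1 - |lambda_i|) Z^Y_i + sqrt(|lambda_i|) sign(lambda_i) Z^shared_i

(components beyond m use lambda_i = 0), so that by construction
var(Xtilde) = I_p, var(Ytilde) = I_q and cov(Xtilde_i, Ytilde_i) = lambda_i:
the signed canonical correlations are direct model parameters.  The observed
vectors are produced by coloring and translation, X = Phi_X^T Xtilde + mu_X
(and likewise for Y), giving var(X) = Phi_X^T Phi_X.

The module also implements the identity-covariance synthetic design used to
probe sign recovery: p = 60, q = 10, Sigma_X = I, Sigma_Y = I, and
Sigma_XY = diag(lambda_i) with alternating signs +lam, -lam, ....
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cca import cca_fit


@dataclass
class GenerativeSpec:
    """Parameters of the two-layer generative model.

    ``lambdas`` may be shorter than min(p, q); missing components are
    non-shared (lambda = 0).  ``Phi_X`` / ``Phi_Y`` default to identity
    mixing (observations are the CCA-whitened variables themselves).
    ``latent_dist`` is ``"gaussian"`` or ``"scaled_t"``; the latter draws
    t(df) variates rescaled by sqrt((df-2)/df) to unit variance (df > 2).
    """

    p: int
    q: int
    lambdas: np.ndarray
    Phi_X: np.ndarray | None = None
    Phi_Y: np.ndarray | None = None
    mu_X: np.ndarray | None = None
    mu_Y: np.ndarray | None = None
    latent_dist: str = "gaussian"
    df: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.lambdas = np.atleast_1d(np.asarray(self.lambdas, dtype=float))
        m = min(self.p, self.q)
        if self.lambdas.size > m:
            raise ValueError(f"at most m = {m} canonical correlations allowed")
        if np.any(np.abs(self.lambdas) > 1):
            raise ValueError("|lambda_i| must be <= 1")
        if self.latent_dist not in ("gaussian", "scaled_t"):
            raise ValueError(f"unknown latent_dist {self.latent_dist!r}")
        if self.latent_dist == "scaled_t" and self.df <= 2:
            raise ValueError(
                f"scaled_t requires df > 2 for finite variance, got df={self.df}"
            )

    @property
    def m(self) -> int:
        return min(self.p, self.q)

    def padded_lambdas(self, k: int) -> np.ndarray:
        """lambdas padded with zeros to length k (components > m are non-shared)."""
        lam = np.zeros(k)
        lam[: self.lambdas.size] = self.lambdas
        return lam


@dataclass
class LatentSample:
    """Draws from the generative model, populated level by level."""

    Z_X: np.ndarray
    Z_Y: np.ndarray
    Z_shared: np.ndarray
    Xtilde: np.ndarray | None = None
    Ytilde: np.ndarray | None = None
    X: np.ndarray | None = None
    Y: np.ndarray | None = None


def _draw(rng: np.random.Generator, spec: GenerativeSpec, n: int, k: int) -> np.ndarray:
    if spec.latent_dist == "gaussian":
        return rng.standard_normal((n, k))
    # rescaled t: unit variance for df > 2
    return rng.standard_t(spec.df, size=(n, k)) * np.sqrt((spec.df - 2.0) / spec.df)


def sample_latent(
    spec: GenerativeSpec, n: int, rng: np.random.Generator | None = None
) -> LatentSample:
    """Draw the level-1 latent variables Z^X, Z^Y, Z^shared (n rows each)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return LatentSample(
        Z_X=_draw(rng, spec, n, spec.p),
        Z_Y=_draw(rng, spec, n, spec.q),
        Z_shared=_draw(rng, spec, n, spec.m),
    )


def mix_level2(latent: LatentSample, lambdas: np.ndarray) -> LatentSample:
    """Mix shared and non-shared latents into the CCA-whitened variables."""
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if np.any(np.abs(lambdas) > 1):
        raise ValueError("|lambda_i| must be <= 1")
    p = latent.Z_X.shape[1]
    q = latent.Z_Y.shape[1]
    m = latent.Z_shared.shape[1]

    def mix(Z_own: np.ndarray, k: int, signed: bool) -> np.ndarray:
        lam = np.zeros(k)
        lam[: lambdas.size] = lambdas
        out = np.sqrt(1.0 - np.abs(lam))[None, :] * Z_own
        shared_w = np.sqrt(np.abs(lam[:m]))
        if signed:
            shared_w = shared_w * np.sign(lam[:m])
        out[:, :m] += shared_w[None, :] * latent.Z_shared
        return out

    latent.Xtilde = mix(latent.Z_X, p, signed=False)
    latent.Ytilde = mix(latent.Z_Y, q, signed=True)
    return latent


def color_observe(latent: LatentSample, spec: GenerativeSpec) -> LatentSample:
    """Color and translate: X = Phi_X^T Xtilde + mu_X (row-wise), same for Y."""
    if latent.Xtilde is None or latent.Ytilde is None:
        raise ValueError("level-2 fields missing; call mix_level2 first")

    def observe(T: np.ndarray, Phi: np.ndarray | None, mu: np.ndarray | None):
        if Phi is not None:
            Phi = np.asarray(Phi, dtype=float)
            if Phi.shape[0] != T.shape[1]:
                raise ValueError(
                    f"mixing matrix has {Phi.shape[0]} rows, level-2 width is "
                    f"{T.shape[1]}"
                )
            T = T @ Phi
        if mu is not None:
            T = T + np.asarray(mu, dtype=float)[None, :]
        return T

    latent.X = observe(latent.Xtilde, spec.Phi_X, spec.mu_X)
    latent.Y = observe(latent.Ytilde, spec.Phi_Y, spec.mu_Y)
    return latent


def simulate(
    spec: GenerativeSpec, n: int, rng: np.random.Generator | None = None
) -> LatentSample:
    """Full forward pass: latents -> whitened level -> observations."""
    latent = sample_latent(spec, n, rng)
    mix_level2(latent, spec.padded_lambdas(spec.m))
    return color_observe(latent, spec)


def alternating_lambdas(q: int, lam: float) -> np.ndarray:
    """Alternating-sign canonical correlations +lam, -lam, +lam, ..."""
    lambdas = np.full(q, float(lam))
    lambdas[1::2] *= -1.0
    return lambdas


def simulate_synthetic_design(
    n: int,
    lam: float,
    *,
    p: int = 60,
    q: int = 10,
    reps: int = 1,
    seed: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Matched (X, Y) pairs from the identity-covariance sign-recovery design.

    X and Y are jointly (p+q)-variate normal with zero mean, Sigma_X = I_p,
    Sigma_Y = I_q and Sigma_XY = diag over the first q components with
    alternating signs +lam, -lam, ... — constructed equivalently through the
    generative model with identity mixing.  Each replicate uses an
    independent counter-based substream of ``seed``.
    """
    if not (0.0 < lam < 1.0):
        raise ValueError(f"lam must be in (0, 1), got {lam}")
    spec = GenerativeSpec(p=p, q=q, lambdas=alternating_lambdas(min(p, q), lam))
    children = np.random.SeedSequence(seed).spawn(reps)
    out = []
    for child in children:
        s = simulate(spec, n, np.random.default_rng(child))
        out.append((s.X, s.Y))
    return out


def _correct_sign_count(
    model, lambdas_true: np.ndarray, p: int, q: int
) -> tuple[int, int]:
    """Count estimated components whose sign matches the truth.

    The estimated sign of component i is correct when sign(lambda_hat_i)
    agrees with the sign of the population correlation of the estimated
    canonical variates, w_X,i^T Sigma_XY w_Y,i, under the true moments
    (Sigma_XY = diag(lambdas_true) over the first q columns).  This needs no
    pairing of components between truth and estimate.
    """
    m = min(p, q)
    # w_X^T Sigma_XY w_Y with diagonal Sigma_XY: sum_j lam_j WX[i, j] WY[i, j]
    truth = np.einsum(
        "ij,ij->i", model.W_X[:, :m] * lambdas_true[None, :m], model.W_Y[:, :m]
    )
    correct = int(np.sum(np.sign(model.lambdas) * np.sign(truth) > 0))
    return correct, m


def sign_recovery_experiment(
    n_grid,
    lam_grid,
    reps: int = 500,
    seed: int | None = None,
    *,
    p: int = 60,
    q: int = 10,
    detail: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo study of signed canonical-correlation recovery.

    For each (n, lam) cell, ``reps`` datasets are drawn from the synthetic
    design, CCA is fitted with shrinkage estimation, and the fraction of the
    m = min(p, q) estimated components with correctly recovered sign is
    pooled across replicates (per-component pooling).

    Returns a long-format table with columns (n, lambda, proportion, reps,
    seed); with ``detail=True`` a per-component table (n, lambda, rep,
    component, correct, est_lambda) instead.
    """
    n_grid = list(n_grid)
    lam_grid = list(lam_grid)
    if not n_grid or not lam_grid or reps < 1:
        raise ValueError("grids must be nonempty and reps >= 1")
    root = np.random.SeedSequence(seed)
    rows = []
    detail_rows = []
    for lam in lam_grid:
        lambdas_true = alternating_lambdas(min(p, q), lam)
        for n in n_grid:
            # one substream per cell, split per replicate
            cell = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(lam_grid.index(lam), n)
            )
            correct_total = 0
            m_total = 0
            for rep, child in enumerate(cell.spawn(reps)):
                spec = GenerativeSpec(p=p, q=q, lambdas=lambdas_true)
                s = simulate(spec, n, np.random.default_rng(child))
                model = cca_fit(s.X, s.Y, estimator="shrinkage")
                correct, m = _correct_sign_count(model, lambdas_true, p, q)
                correct_total += correct
                m_total += m
                if detail:
                    truth = np.einsum(
                        "ij,ij->i",
                        model.W_X[:, :m] * lambdas_true[None, :m],
                        model.W_Y[:, :m],
                    )
                    ok = np.sign(model.lambdas) * np.sign(truth) > 0
                    for comp in range(m):
                        detail_rows.append(
                            dict(n=n, **{"lambda": lam}, rep=rep,
                                 component=comp + 1, correct=bool(ok[comp]),
                                 est_lambda=model.lambdas[comp])
                        )
            rows.append(
                dict(n=n, **{"lambda": lam},
                     proportion=correct_total / m_total, reps=reps, seed=seed)
            )
    return pd.DataFrame(detail_rows if detail else rows)
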