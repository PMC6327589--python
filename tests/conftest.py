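import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_psd(rng, p, cond=None, min_var=0.5, max_var=4.0):
    """Random PSD covariance with distinct, strictly positive variances."""
    A = rng.standard_normal((p, p))
    S = A @ A.T / p + 0.1 * np.eye(p)
    v = np.linspace(min_var, max_var, p)
    d = np.sqrt(v / np.diag(S))
    return S * np.outer(d, d)


def random_joint_correlation(rng, p, q, strength=0.5):
    """Random PSD joint correlation matrix, split into blocks."""
    k = p + q
    A = rng.standard_normal((k, 2 * k))
    S = A @ A.T
    s = np.sqrt(np.diag(S))
    R = S / np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return R[:p, :p], R[:p, p:], R[p:, p:]
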