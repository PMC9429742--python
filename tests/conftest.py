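import numpy as np
import pytest

from snpset.ld import LdMatrix


def ar_block_corr(m: int, rho: float = 0.9, block: int = 25) -> np.ndarray:
    """Block-diagonal AR(1) correlation matrix."""
    r = np.eye(m)
    for b0 in range(0, m, block):
        idx = np.arange(b0, min(b0 + block, m))
        r[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
    return r


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def ld_identity_2():
    return LdMatrix.identity(2)


@pytest.fixture
def ld_ar_small():
    """Shrunk strong-LD matrix, M=10."""
    r = 0.95 * ar_block_corr(10, rho=0.9, block=5) + 0.05 * np.eye(10)
    return LdMatrix(r, n_ref=None, delta=0.95)


def mvn_draws(r: np.ndarray, n: int, seed: int) -> np.ndarray:
    w, v = np.linalg.eigh(r)
    l = v * np.sqrt(np.clip(w, 0, None))
    return np.random.default_rng(seed).standard_normal((n, r.shape[0])) @ l.T
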