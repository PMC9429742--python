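"""Linkage-disequilibrium estimation from a reference panel.

The empirical SNP correlation matrix R-hat = G'G/(n-1) of column-standardised
dosages is ill-conditioned when the reference panel is small, which inflates
LD-dependent tests.  All LD-dependent tests therefore consume the linearly
shrunk estimator

    R = delta * R-hat + (1 - delta) * I,     delta = 0.95 by default,

whose smallest eigenvalue is at least 1 - delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datatypes import GenotypePanel

DEFAULT_DELTA = 0.95


@dataclass
class LdMatrix:
    r: np.ndarray
    n_ref: Optional[int] = None
    delta: float = 0.0  # shrinkage already applied (0 = raw)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("LD matrix must be square")
        if np.max(np.abs(self.r - self.r.T)) > 1e-8:
            raise ValueError("LD matrix must be symmetric")
        if np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-8:
            raise ValueError("LD matrix must have unit diagonal")

    @property
    def m(self) -> int:
        return self.r.shape[0]

    @classmethod
    def identity(cls, m: int) -> "LdMatrix":
        return cls(r=np.eye(m), n_ref=None, delta=1.0)


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per SNP, then centre and scale columns."""
    g = np.array(matrix, dtype=float)
    if np.isnan(g).any():
        col_mean = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = col_mean[idx[1]]
    mu = g.mean(axis=0)
    sd = g.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"constant genotype column at index {bad}")
    return (g - mu) / sd


def empirical_ld(panel: GenotypePanel | np.ndarray, snp_ids=None) -> LdMatrix:
    """Raw LD, R-hat = G'G/(n-1), of column-standardised dosages.

    A symmetric eigenvalue clip at zero absorbs numerical asymmetry before
    any later shrinkage.
    """
    if isinstance(panel, GenotypePanel):
        if snp_ids is not None:
            panel = panel.subset(snp_ids)
        matrix = panel.matrix
    else:
        matrix = np.asarray(panel, dtype=float)
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("reference panel must contain at least 3 individuals")
    g = standardize(matrix)
    r = g.T @ g / (n - 1)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    # clip tiny negative eigenvalues from round-off
    w = np.linalg.eigvalsh(r)
    if w[0] < -1e-10:
        w2, v = np.linalg.eigh(r)
        r = (v * np.clip(w2, 0.0, None)) @ v.T
        r = 0.5 * (r + r.T)
        np.fill_diagonal(r, 1.0)
    return LdMatrix(r=r, n_ref=n, delta=0.0)


def shrink_ld(raw: LdMatrix, delta: float = DEFAULT_DELTA) -> LdMatrix:
    """R = delta * R_raw + (1 - delta) * I."""
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    r = delta * raw.r + (1.0 - delta) * np.eye(raw.m)
    return LdMatrix(r=r, n_ref=raw.n_ref, delta=delta)


def reference_ld(
    panel: GenotypePanel | np.ndarray, snp_ids=None, delta: float = DEFAULT_DELTA
) -> LdMatrix:
    """Convenience: empirical LD followed by shrinkage."""
    return shrink_ld(empirical_ld(panel, snp_ids), delta=delta)
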