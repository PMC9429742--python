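"""Core domain containers shared by all modules.

These are deliberately small dataclasses around numpy arrays / pandas
indices; all heavy lifting lives in the estimator classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

P_Z_TOL = 1e-8  # declared consistency tolerance between z and p


def z_to_p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value, p = 2*Phi(-|z|)."""
    return 2.0 * stats.norm.sf(np.abs(z))


def p_to_z(p: np.ndarray, sign: np.ndarray | None = None) -> np.ndarray:
    """|z| from a two-sided p-value, optionally signed."""
    z = stats.norm.isf(np.asarray(p, dtype=float) / 2.0)
    if sign is not None:
        z = z * np.sign(sign)
    return z


@dataclass
class SummaryStats:
    """Marginal GWAS summary statistics for one SNP set.

    z and p must be mutually consistent (p = 2*Phi(-|z|)); this is checked
    on construction when both are supplied.
    """

    snp_ids: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n: Optional[int] = None
    maf: Optional[np.ndarray] = None

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids)
        self.z = np.asarray(self.z, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if not (len(self.snp_ids) == len(self.z) == len(self.p)):
            raise ValueError("snp_ids, z and p must have equal length")
        if len(self.z) < 1:
            raise ValueError("a SNP set must contain at least one SNP")
        if np.any((self.p <= 0) | (self.p > 1)):
            raise ValueError("p values must lie in (0, 1]")
        if np.max(np.abs(self.p - z_to_p(self.z))) > P_Z_TOL:
            raise ValueError("z and p are inconsistent (p != 2*Phi(-|z|))")
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float)
            if np.any((self.maf <= 0) | (self.maf > 0.5)):
                raise ValueError("maf must lie in (0, 0.5]")

    @property
    def m(self) -> int:
        return len(self.z)

    @classmethod
    def from_z(cls, z, snp_ids=None, n=None, maf=None) -> "SummaryStats":
        z = np.asarray(z, dtype=float)
        if snp_ids is None:
            snp_ids = np.array([f"snp{i}" for i in range(len(z))])
        return cls(snp_ids=snp_ids, z=z, p=z_to_p(z), n=n, maf=maf)


@dataclass
class GenotypePanel:
    """Additive dosage matrix (individuals x SNPs) with SNP metadata."""

    matrix: np.ndarray
    snp_ids: np.ndarray
    positions: np.ndarray
    maf: np.ndarray = field(default=None)
    chrom: Optional[np.ndarray] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (individuals x SNPs)")
        if self.matrix.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids length must match number of columns")
        if self.maf is None:
            self.maf = compute_maf(self.matrix)
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    def subset(self, snp_ids: Sequence) -> "GenotypePanel":
        idx = {s: i for i, s in enumerate(self.snp_ids)}
        cols = np.array([idx[s] for s in snp_ids], dtype=int)
        return GenotypePanel(
            matrix=self.matrix[:, cols],
            snp_ids=self.snp_ids[cols],
            positions=self.positions[cols],
            maf=self.maf[cols],
            chrom=None if self.chrom is None else self.chrom[cols],
        )


def compute_maf(matrix: np.ndarray) -> np.ndarray:
    """Minor allele frequency per SNP column from non-missing dosages."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(matrix, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


@dataclass
class GeneSet:
    """A gene with the SNPs assigned to its (extended) window."""

    gene_id: str
    chrom: str
    start: int
    end: int
    snp_ids: np.ndarray

    @property
    def m(self) -> int:
        return len(self.snp_ids)


@dataclass
class TestResult:
    """Outcome of one SNP-set test."""

    method: str
    stat: float
    p: float
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.stat):
            raise ValueError(f"{self.method}: non-finite statistic")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.method}: p-value {self.p} outside (0, 1]")
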