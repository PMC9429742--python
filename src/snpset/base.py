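"""Scikit-learn style base class for SNP-set tests.

Every test is an estimator: ``fit`` consumes the LD information (a reference
dosage panel, a precomputed :class:`~snpset.ld.LdMatrix`, or a square
correlation matrix) and precomputes whatever eigenstructure the method needs;
``transform`` maps a batch of marginal Z-score vectors — one row per SNP set
replicate — to ``[statistic, p-value]`` rows.  ``test`` wraps a single
:class:`~snpset.datatypes.SummaryStats` into a :class:`TestResult`.

LD-free p-value combiners ignore the LD argument of ``fit`` (they accept
``X=None``) and may be driven directly with p-values via
``transform_pvalues``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import SummaryStats, TestResult, z_to_p
from .ld import DEFAULT_DELTA, LdMatrix, reference_ld


class BaseSetTest(BaseEstimator):
    method: str = "?"
    requires_ld: bool = True
    requires_n: bool = False

    def _resolve_ld(self, X) -> LdMatrix | None:
        if X is None:
            return None
        if isinstance(X, LdMatrix):
            return X
        X = np.asarray(X, dtype=float)
        if (
            X.ndim == 2
            and X.shape[0] == X.shape[1]
            and np.allclose(np.diag(X), 1.0, atol=1e-8)
            and np.allclose(X, X.T, atol=1e-8)
        ):
            return LdMatrix(r=X, n_ref=None, delta=getattr(self, "delta", 1.0))
        delta = getattr(self, "delta", DEFAULT_DELTA)
        return reference_ld(X, delta=delta)

    # -- sklearn plumbing -------------------------------------------------
    def fit(self, X=None, y=None):
        """Fit to LD information.  X: reference dosage panel (n_ref x M),
        LdMatrix, square correlation matrix, or None for LD-free tests."""
        ld = self._resolve_ld(X)
        if self.requires_ld and ld is None:
            raise ValueError(f"{self.method} requires LD information")
        self.ld_ = ld
        self.m_ = None if ld is None else ld.m
        self._prepare()
        return self

    def _prepare(self):  # subclass hook
        pass

    def _weight_vector(self, m: int) -> np.ndarray:
        w = getattr(self, "weights", None)
        if w is None:
            return np.ones(m)
        w = np.asarray(w, dtype=float)
        if w.shape != (m,):
            raise ValueError("weights length does not match number of SNPs")
        peak = np.max(np.abs(w))
        if peak > 0:
            # the weighted statistics are invariant to the overall weight
            # scale; normalising guards against under/overflow
            w = w / peak
        return w

    # -- main API ----------------------------------------------------------
    def transform(self, Z) -> np.ndarray:
        """Map Z-score rows (n_sets, M) to [stat, p] rows (n_sets, 2)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        stats_, ps = self._transform_z(Z)
        return np.column_stack([stats_, ps])

    def _transform_z(self, Z):  # pragma: no cover - abstract
        raise NotImplementedError

    def test(self, ss: SummaryStats, **kw) -> TestResult:
        """Run the test on one summary-statistics set."""
        if self.requires_n and getattr(self, "n", None) is None:
            if ss.n is None:
                raise ValueError(f"{self.method} requires the GWAS sample size")
            self.n = int(ss.n)
            self._prepare()
        out = self.transform(ss.z[None, :])
        detail = dict(self._last_detail) if hasattr(self, "_last_detail") else {}
        return TestResult(method=self.method, stat=float(out[0, 0]),
                          p=float(out[0, 1]), detail=detail)


class PCombTest(BaseSetTest):
    """Base for LD-free p-value combination tests."""

    requires_ld = False

    def _transform_z(self, Z):
        return self._transform_p(z_to_p(Z))

    def transform_pvalues(self, P) -> np.ndarray:
        P = np.atleast_2d(np.asarray(P, dtype=float))
        stats_, ps = self._transform_p(P)
        return np.column_stack([stats_, ps])

    def _transform_p(self, P):  # pragma: no cover - abstract
        raise NotImplementedError


P_CLIP = 1e-15


def clip_pvalues(P: np.ndarray) -> np.ndarray:
    """Clip p-values into [1e-15, 1 - 1e-15] before transforms."""
    return np.clip(P, P_CLIP, 1.0 - P_CLIP)
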