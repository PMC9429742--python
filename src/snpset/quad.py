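"""LD-dependent linear and quadratic Z-score combination tests.

* Burden (BT): T = w'Z / sqrt(w'Rw), standard normal null.
* SKAT: Q = sum (w_j Z_j)^2, mixture-of-chi-square null with eigenvalues of
  D_w R D_w.
* SKAT-O: the minimum p-value over the family Q_rho = (1-rho) Q_SKAT +
  rho Q_burden^2, with the omnibus p-value from the one-dimensional
  conditional integration of Lee et al.'s decomposition.
* MLR: joint fixed-effects regression statistic Z' R^{-1} Z on the F scale
  with (M, n-1-M) degrees of freedom.
* FLM: the same F-form after projecting onto a cubic B-spline basis over
  SNP positions.
* DOT: decorrelation Z -> R^{-1/2} Z, chi-square with M degrees of freedom.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from .base import BaseSetTest
from .datatypes import z_to_p
from .tails import MixtureChi2, liu_isf, mixture_chi2_tail

_TINY = np.finfo(float).tiny

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


class BurdenTest(BaseSetTest):
    """Linear combination of Z-scores; powerful under shared effect sign."""

    method = "BT"

    def __init__(self, delta=0.95, weights=None):
        self.delta = delta
        self.weights = weights

    def _prepare(self):
        w = self._weight_vector(self.m_)
        denom = float(w @ self.ld_.r @ w)
        if denom <= 1e-12:
            raise ValueError("degenerate weights: w'Rw <= 0")
        self.w_ = w
        self.denom_ = denom

    def _transform_z(self, Z):
        t = Z @ self.w_ / np.sqrt(self.denom_)
        return t, np.maximum(z_to_p(t), _TINY)


class SkatTest(BaseSetTest):
    """Variance-component score test: weighted sum of squared Z-scores."""

    method = "SKAT"

    def __init__(self, delta=0.95, weights=None, tail_method="davies",
                 batch_interp=True):
        self.delta = delta
        self.weights = weights
        self.tail_method = tail_method
        self.batch_interp = batch_interp

    def _prepare(self):
        w = self._weight_vector(self.m_)
        if np.all(w == 0):
            raise ValueError("all-zero weights")
        sigma = (w[:, None] * self.ld_.r) * w[None, :]
        lam = np.linalg.eigvalsh(sigma)
        lam = np.clip(lam, 0.0, None)
        self.w_ = w
        self.mix_ = MixtureChi2(lam)

    def _transform_z(self, Z):
        q = np.square(Z * self.w_).sum(axis=1)
        if Z.shape[0] > 4 and self.batch_interp:
            p = self.mix_.sf_batch(q)
            self._last_detail = {"tail": "davies-grid"}
        else:
            p = np.empty_like(q)
            for i, qi in enumerate(q):
                p[i], used = mixture_chi2_tail(
                    self.mix_.lambdas, qi, method=self.tail_method
                )
                self._last_detail = {"tail": used}
        return q, p


class SkatOTest(BaseSetTest):
    """Optimal SKAT: adaptive combination of SKAT and the squared burden.

    Implements the conditional one-dimensional integration of the optimal
    test: Q_rho decomposes as (1-rho)*kappa + tau(rho)*eta0 with eta0 a
    chi-square(1) variable, kappa approximated by its matched mixture of
    chi-squares, and the omnibus p-value is one minus the probability that
    every Q_rho stays below its level-T quantile, T being the minimum of the
    component p-values.
    """

    method = "SKATO"

    def __init__(self, delta=0.95, weights=None, rho_grid=DEFAULT_RHO_GRID,
                 n_nodes=80):
        self.delta = delta
        self.weights = weights
        self.rho_grid = rho_grid
        self.n_nodes = n_nodes

    def _prepare(self):
        rho = np.asarray(sorted(self.rho_grid), dtype=float)
        if np.any((rho < 0) | (rho > 1)):
            raise ValueError("rho grid must lie in [0, 1]")
        w = self._weight_vector(self.m_)
        if np.all(w == 0):
            raise ValueError("all-zero weights")
        m = self.m_
        sigma = (w[:, None] * self.ld_.r) * w[None, :]
        ew, V = np.linalg.eigh(sigma)
        ew = np.clip(ew, 0.0, None)
        sqrt_sigma = (V * np.sqrt(ew)) @ V.T
        v1 = sqrt_sigma @ np.ones(m)

        # per-rho component mixtures
        self.rho_ = rho
        self.mix_rho_ = []
        for r in rho:
            s_r = (1.0 - r) * sigma + r * np.outer(v1, v1)
            lam_r = np.clip(np.linalg.eigvalsh(s_r), 0.0, None)
            self.mix_rho_.append(MixtureChi2(lam_r))

        # Lee decomposition pieces (only needed when the grid has > 1 rho)
        z1 = np.sqrt(ew)[:, None] * V.T  # Z1' Z1 = sigma
        zbar = z1.mean(axis=1)
        zbar_sq = float(zbar @ zbar)
        self.w_ = w
        self.sigma_ = sigma
        self.sum_sigma_ = float(np.sum(sigma))
        self.degenerate_burden_ = zbar_sq < 1e-12
        if self.degenerate_burden_ or len(rho) == 1:
            return
        cof1 = z1.T @ zbar / zbar_sq
        z2 = z1 - np.outer(zbar, cof1)
        k2 = z2.T @ z2
        lam_k = np.clip(np.linalg.eigvalsh(k2), 0.0, None)
        lam_k = lam_k[lam_k > 1e-12 * max(lam_k.max(), 1e-300)]
        self.mix_kappa_ = MixtureChi2(lam_k)
        self.mu_q_ = float(lam_k.sum())
        var_zeta = 4.0 * zbar_sq * float(cof1 @ k2 @ cof1)
        var_core = 2.0 * float(np.sum(lam_k**2))
        self.adj_ = np.sqrt(var_core / (var_core + var_zeta))
        self.tau_ = zbar_sq * (m**2 * rho + (1.0 - rho) * float(cof1 @ cof1))

    def _transform_z(self, Z):
        u = Z * self.w_
        q_skat = np.square(u).sum(axis=1)
        q_burden = np.square(u.sum(axis=1))
        rho = self.rho_
        n_sets = Z.shape[0]

        if len(rho) == 1:
            mix = self.mix_rho_[0]
            q = (1.0 - rho[0]) * q_skat + rho[0] * q_burden
            p = mix.sf_batch(q) if n_sets > 4 else np.array(
                [mix.sf(qi) for qi in q]
            )
            self._last_detail = {"rho_argmin": float(rho[0])}
            return q, p

        q_rho = (1.0 - rho[None, :]) * q_skat[:, None] + rho[None, :] * q_burden[:, None]
        # scalar calls avoid the grid interpolants (exact tails + Liu
        # quantiles); batches amortise the interpolant builds
        scalar = n_sets <= 4 and self.mix_rho_[0]._interp is None
        p_rho = np.empty_like(q_rho)
        for j, mix in enumerate(self.mix_rho_):
            if scalar:
                # fast per-gene route: saddlepoint component tails
                p_rho[:, j] = [
                    mixture_chi2_tail(mix.lambdas, qv, method="saddlepoint")[0]
                    for qv in q_rho[:, j]
                ]
            else:
                p_rho[:, j] = mix.sf_batch(q_rho[:, j])
        t_min = p_rho.min(axis=1)
        argmin = rho[p_rho.argmin(axis=1)]

        if self.degenerate_burden_:
            # burden direction carries no variance; SKAT-O collapses to SKAT
            p = np.clip(t_min * len(rho), _TINY, 1.0)
            self._last_detail = {"rho_argmin": float(argmin[0]),
                                 "note": "degenerate burden direction"}
            return t_min, p

        # level-T quantiles of every component
        q_min = np.empty_like(q_rho)
        for j, mix in enumerate(self.mix_rho_):
            if scalar:
                q_min[:, j] = [liu_isf(mix.lambdas, t) for t in t_min]
            else:
                q_min[:, j] = mix.isf_batch(t_min)

        # conditional integration over eta0 = x = u^2, u half-normal
        has_one = rho[-1] >= 1.0 - 1e-12
        if has_one:
            x_max = q_min[:, -1] / self.tau_[-1]
        else:
            x_max = np.full(n_sets, 250.0)
        x_max = np.minimum(x_max, 250.0)
        u_max = np.sqrt(x_max)

        nodes, weights = np.polynomial.legendre.leggauss(self.n_nodes)
        # map to [0, u_max] per replicate
        uu = 0.5 * (nodes[None, :] + 1.0) * u_max[:, None]
        ww = 0.5 * u_max[:, None] * weights[None, :]
        x = uu**2

        idx = slice(0, len(rho) - 1) if has_one else slice(0, len(rho))
        rho_in = rho[idx]
        tau_in = self.tau_[idx]
        thresh = (
            q_min[:, idx, None] - tau_in[None, :, None] * x[:, None, :]
        ) / (1.0 - rho_in[None, :, None])
        vmin = thresh.min(axis=1)  # (n_sets, n_nodes)
        q_adj = (vmin - self.mu_q_) * self.adj_ + self.mu_q_
        if scalar:
            from .tails import _saddlepoint_sf

            lam_k = self.mix_kappa_.lambdas
            flat = np.array([
                0.0 if v <= 0 else 1.0 - _saddlepoint_sf(lam_k, v)
                for v in q_adj.ravel()
            ])
            f_kappa = flat.reshape(q_adj.shape)
        else:
            f_kappa = np.where(
                q_adj <= 0.0, 0.0,
                1.0 - self.mix_kappa_.sf_batch(np.maximum(q_adj, 1e-300)),
            )
        integral = np.sum(f_kappa * 2.0 * stats.norm.pdf(uu) * ww, axis=1)
        p = np.clip(1.0 - integral, _TINY, 1.0)
        # the omnibus p can never be smaller than T itself
        p = np.maximum(p, t_min)
        self._last_detail = {"rho_argmin": float(argmin[0])}
        return t_min, p


def burden_test(ss, ld, w=None):
    return BurdenTest(weights=_w(w)).fit(ld).test(ss)


def skat_test(ss, ld, w=None):
    return SkatTest(weights=_w(w)).fit(ld).test(ss)


def skato_test(ss, ld, w=None, rho_grid=DEFAULT_RHO_GRID):
    return SkatOTest(weights=_w(w), rho_grid=rho_grid).fit(ld).test(ss)


def mlr_test(ss, ld, n=None):
    return MlrTest(n=n if n is not None else ss.n).fit(ld).test(ss)


def flm_test(ss, ld, n=None, positions=None, basis_k=25):
    return FlmTest(
        n=n if n is not None else ss.n, positions=positions, basis_k=basis_k
    ).fit(ld).test(ss)


def dot_test(ss, ld):
    return DotTest().fit(ld).test(ss)


def _w(w):
    if w is None:
        return None
    return w.w if hasattr(w, "w") else np.asarray(w, dtype=float)


def mixture_chi2_tail_op(lambdas, q, method="davies"):
    """Spec-level alias of the mixture tail engine."""
    return mixture_chi2_tail(lambdas, q, method=method)


class MlrTest(BaseSetTest):
    """Joint multiple-regression test from summary statistics."""

    method = "MLR"
    requires_n = True

    def __init__(self, delta=0.95, n=None):
        self.delta = delta
        self.n = n

    def _prepare(self):
        self.rinv_ = np.linalg.inv(self.ld_.r)

    def _q_form(self, Z):
        return np.einsum("ij,jk,ik->i", Z, self.rinv_, Z)

    def _transform_z(self, Z):
        n, m = int(self.n), self.m_
        if n <= m + 1:
            raise ValueError("MLR requires n > M + 1")
        q = self._q_form(Z)
        df2 = n - 1 - m
        sat = q >= n - 1
        qc = np.minimum(q, (n - 1) * (1 - 1e-12))
        f = (df2 / m) * qc / ((n - 1) - qc)
        p = stats.f.sf(f, m, df2)
        p = np.where(sat, _TINY, np.maximum(p, _TINY))
        if np.any(sat):
            self._last_detail = {"flag": "statistic at saturation bound"}
        return f, p


class FlmTest(BaseSetTest):
    """Functional regression: B-spline smoothed joint test."""

    method = "FLM"
    requires_n = True

    def __init__(self, delta=0.95, n=None, positions=None, basis_k=25):
        self.delta = delta
        self.n = n
        self.positions = positions
        self.basis_k = basis_k

    @staticmethod
    def _bspline_basis(positions, k):
        """Cubic B-spline design matrix with k columns at min-max scaled
        positions."""
        pos = np.asarray(positions, dtype=float)
        span = pos.max() - pos.min()
        x = (pos - pos.min()) / span if span > 0 else np.zeros_like(pos)
        degree = 3
        n_inner = k - (degree + 1)
        inner = np.linspace(0, 1, n_inner + 2)[1:-1] if n_inner > 0 else []
        knots = np.concatenate(
            [np.zeros(degree + 1), inner, np.ones(degree + 1)]
        )
        return BSpline.design_matrix(x, knots, degree).toarray()

    def _prepare(self):
        m = self.m_
        k = min(self.basis_k, m)
        if self.positions is None or k >= m or k <= 4:
            # basis collapses to the identity: identical to MLR
            b = np.eye(m)
            k = m
        else:
            b = self._bspline_basis(self.positions, k)
        self.k_ = k
        core = b.T @ self.ld_.r @ b
        try:
            core_inv = np.linalg.inv(core)
        except np.linalg.LinAlgError as e:
            raise ValueError("singular B'RB basis Gram matrix") from e
        self.proj_ = b @ core_inv @ b.T

    def _transform_z(self, Z):
        n, k = int(self.n), self.k_
        if n <= k + 1:
            raise ValueError("FLM requires n > basis_k + 1")
        q = np.einsum("ij,jk,ik->i", Z, self.proj_, Z)
        df2 = n - 1 - k
        sat = q >= n - 1
        qc = np.minimum(q, (n - 1) * (1 - 1e-12))
        f = (df2 / k) * qc / ((n - 1) - qc)
        p = np.where(sat, _TINY, np.maximum(stats.f.sf(f, k, df2), _TINY))
        return f, p


class DotTest(BaseSetTest):
    """Decorrelation by orthogonal transformation: chi-square(M) on
    R^{-1/2} Z."""

    method = "DOT"

    def __init__(self, delta=0.95):
        self.delta = delta

    def _prepare(self):
        self.rinv_ = np.linalg.inv(self.ld_.r)

    def _transform_z(self, Z):
        s = np.einsum("ij,jk,ik->i", Z, self.rinv_, Z)
        p = np.maximum(stats.chi2.sf(s, self.m_), _TINY)
        return s, p
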