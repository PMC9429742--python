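"""LD-aware order-statistic tests.

Higher-criticism and Berk-Jones statistics scan the ordered marginal
p-values for an excess of moderately small values; their analytic p-values
under independence are exact boundary-crossing probabilities of uniform
order statistics, computed by a Markov count-chain recursion.  The
generalised variants (GHC, GBJ) adjust the exceedance-count variance for LD
through a Hermite-series expansion of the two-sided exceedance covariance
and obtain p-values from a seeded multivariate-normal Monte-Carlo null when
the LD matrix is not the identity.  minP, GATES and SimpleM are
minimum-p-based procedures with LD-adjusted multiplicity corrections.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .base import BaseSetTest, clip_pvalues
from .datatypes import z_to_p

_TINY = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# boundary-crossing engine (independence null)
# ---------------------------------------------------------------------------

def _count_noncrossing(m: int, thresholds: np.ndarray, limits: np.ndarray) -> float:
    """P(N(t_i) <= limits[i] for all i) where N(t) counts how many of m iid
    uniforms fall at or below t.  Thresholds must be sorted ascending.
    Exact Markov recursion over the counts; O(len(thresholds) * m^2)."""
    dist = np.zeros(m + 1)
    dist[0] = 1.0
    t_prev = 0.0
    counts = np.arange(m + 1)
    lgam = special.gammaln(np.arange(m + 2))
    l = counts[:, None]
    k = counts[None, :]
    d = k - l
    for t, lim in zip(thresholds, limits):
        if lim < 0:
            return 0.0
        t = min(max(float(t), 0.0), 1.0)
        if t > t_prev:
            s = (t - t_prev) / (1.0 - t_prev)
            if s >= 1.0:
                dist = np.concatenate([np.zeros(m), [dist.sum()]])
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    logpmf = (
                        lgam[m - l + 1]
                        - lgam[d + 1]
                        - lgam[m - k + 1]
                        + d * np.log(s)
                        + (m - k) * np.log1p(-s)
                    )
                pmf = np.exp(np.where(d >= 0, logpmf, -np.inf))
                dist = dist @ pmf
            t_prev = t
        if lim < m:
            dist[int(lim) + 1 :] = 0.0
        if not np.any(dist):
            return 0.0
    return float(dist.sum())


def uniform_noncrossing_prob(bounds: np.ndarray) -> float:
    """P(U_(j) > b_j for all j) for M iid uniforms, with ``bounds[j-1]`` the
    lower boundary for the j-th order statistic (sorted ascending)."""
    b = np.asarray(bounds, dtype=float)
    m = b.size
    order = np.argsort(b, kind="stable")
    return _count_noncrossing(m, b[order], np.asarray(order, dtype=int))


def _hc_boundary(m: int, h: float) -> np.ndarray:
    """Solve (j - M b)/sqrt(M b (1-b)) = h for b, j = 1..M."""
    j = np.arange(1, m + 1, dtype=float)
    a = m**2 + h**2 * m
    bq = 2.0 * j * m + h**2 * m
    cq = j**2
    disc = np.sqrt(np.maximum(bq**2 - 4.0 * a * cq, 0.0))
    if h >= 0:
        b = (bq - disc) / (2.0 * a)
    else:
        b = (bq + disc) / (2.0 * a)
    return np.clip(b, 0.0, 1.0)


def _bj_kl(t, x):
    """K(t, x) = t log(t/x) + (1-t) log((1-t)/(1-x)); t may equal 1."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        first = t * (np.log(t) - np.log(x))
        second = np.where(t >= 1.0, 0.0, (1 - t) * (np.log1p(-t) - np.log1p(-x)))
    return first + second


def _bj_boundary(m: int, s: float) -> np.ndarray:
    """Solve M*K(j/M, b) = s for b in (0, j/M)."""
    from scipy.optimize import brentq

    out = np.empty(m)
    for i in range(m):
        t = (i + 1) / m
        f = lambda x: m * _bj_kl(t, x) - s
        lo = 1e-300
        if f(t * (1 - 1e-12)) > 0:  # no root below t: boundary collapses
            out[i] = t
            continue
        out[i] = brentq(f, lo, t * (1 - 1e-12), xtol=1e-16, rtol=1e-12)
    return out


def hc_crossing_pvalue(m: int, h: float) -> float:
    """P(HC >= h) under the independence null, for the HC statistic whose
    maximisation range excludes p_(j) <= 1/M.

    The event is {exists j: 1/M < p_(j) <= b_j(h)}.  Conditioning on
    a = #{p_i <= 1/M} (binomial, truncated once its tail is negligible)
    reduces each slice to a standard boundary-noncrossing computation for
    the remaining M - a uniforms on (1/M, 1]."""
    if not np.isfinite(h):
        return 1.0 if h < 0 else _TINY
    b = _hc_boundary(m, h)
    u = 1.0 / m
    js = np.where(b > u)[0] + 1  # 1-based constraint indices
    if js.size == 0:
        return _TINY
    total_nc = 0.0
    cum = 0.0
    for a in range(0, m + 1):
        pa = float(stats.binom.pmf(a, m, u))
        jlist = js[js > a]
        if jlist.size == 0:
            nc = 1.0
        else:
            th = (b[jlist - 1] - u) / (1.0 - u)
            order = np.argsort(th, kind="stable")
            nc = _count_noncrossing(m - a, th[order], (jlist - 1 - a)[order])
        total_nc += pa * nc
        cum += pa
        if 1.0 - cum < 1e-13:
            break
    total_nc += 1.0 - cum  # remaining slices bounded by nc <= 1
    return min(max(1.0 - total_nc, _TINY), 1.0)


def bj_crossing_pvalue(m: int, s: float) -> float:
    """P(BJ >= s) under the independence null."""
    if s <= 1e-12:
        return 1.0
    return min(max(1.0 - uniform_noncrossing_prob(_bj_boundary(m, s)), _TINY), 1.0)


# ---------------------------------------------------------------------------
# statistics (vectorised over rows of sorted p-values)
# ---------------------------------------------------------------------------

def _sorted_p(P: np.ndarray) -> np.ndarray:
    return np.sort(clip_pvalues(P), axis=1)


def hc_stat_rows(Ps: np.ndarray) -> np.ndarray:
    """HC statistic per row of ascending-sorted p-values; the maximisation
    excludes p_(j) <= 1/M (falling back to the full range when the
    restriction empties it)."""
    b, m = Ps.shape
    j = np.arange(1, m + 1)
    vals = np.sqrt(m) * (j / m - Ps) / np.sqrt(Ps * (1.0 - Ps))
    allowed = Ps > 1.0 / m
    masked = np.where(allowed, vals, -np.inf)
    out = masked.max(axis=1)
    empty = ~allowed.any(axis=1)
    if np.any(empty):
        out[empty] = vals[empty].max(axis=1)
    return out


def bj_stat_rows(Ps: np.ndarray) -> np.ndarray:
    b, m = Ps.shape
    t = np.arange(1, m + 1) / m
    kl = m * _bj_kl(t[None, :], Ps)
    masked = np.where(Ps < t[None, :], kl, -np.inf)
    out = masked.max(axis=1)
    return np.maximum(out, 0.0)


_HERMITE_ODD = {
    2: np.polynomial.hermite_e.HermiteE([0, 1]),
    4: np.polynomial.hermite_e.HermiteE([0, 0, 0, 1]),
    6: np.polynomial.hermite_e.HermiteE([0, 0, 0, 0, 0, 1]),
    8: np.polynomial.hermite_e.HermiteE([0, 0, 0, 0, 0, 0, 0, 1]),
    10: np.polynomial.hermite_e.HermiteE([0, 0, 0, 0, 0, 0, 0, 0, 0, 1]),
}


def exceedance_variance(t: np.ndarray, m: int, r_pow_sums: dict) -> np.ndarray:
    """Var of the two-sided exceedance count S(t) = #{|Z_i| > t} for
    Z ~ N(0, R), via the Hermite expansion of the indicator covariance
    truncated at order 10.  ``r_pow_sums[n]`` = sum_{i != j} r_ij^n."""
    t = np.asarray(t, dtype=float)
    pt = 2.0 * stats.norm.sf(t)
    var = m * pt * (1.0 - pt)
    phi2 = stats.norm.pdf(t) ** 2
    acc = np.zeros_like(t)
    for n, he in _HERMITE_ODD.items():
        acc += he(t) ** 2 / special.factorial(n) * r_pow_sums[n]
    return var + 4.0 * phi2 * acc


# ---------------------------------------------------------------------------
# MVN null sampler
# ---------------------------------------------------------------------------

class MvnNullSampler:
    """Seeded sampler of null Z-vectors ~ N(0, R) used for simulation-based
    p-values; draws are chunked and reproducible given the seed."""

    def __init__(self, r: np.ndarray, n_draws: int = 100_000, seed: int = 1234):
        self.r = np.asarray(r, dtype=float)
        self.n_draws = int(n_draws)
        self.seed = int(seed)
        w, v = np.linalg.eigh(self.r)
        self.chol_like_ = v * np.sqrt(np.clip(w, 0.0, None))

    def draws(self, chunk: int = 20_000):
        rng = np.random.default_rng(self.seed)
        left = self.n_draws
        while left > 0:
            b = min(chunk, left)
            yield rng.standard_normal((b, self.r.shape[0])) @ self.chol_like_.T
            left -= b

    def null_stats(self, stat_fn) -> np.ndarray:
        out = []
        for z in self.draws():
            out.append(stat_fn(z))
        return np.concatenate(out)


def mc_pvalue(null_stats: np.ndarray, obs: np.ndarray):
    """(1 + #null >= obs) / (n + 1) with its Monte-Carlo standard error."""
    ns = np.sort(null_stats)
    n = ns.size
    obs = np.atleast_1d(obs)
    count = n - np.searchsorted(ns, obs, side="left")
    p = (1.0 + count) / (n + 1.0)
    se = np.sqrt(p * (1.0 - p) / n)
    return p, se


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _ScanTestBase(BaseSetTest):
    """Shared machinery for HC/BJ-type scan tests and their LD-aware
    generalisations."""

    def __init__(self, delta=0.95, n_draws=100_000, seed=1234):
        self.delta = delta
        self.n_draws = n_draws
        self.seed = seed

    generalized: bool = False

    def _prepare(self):
        r = self.ld_.r
        off = r[~np.eye(self.m_, dtype=bool)]
        self.independent_ = off.size == 0 or np.max(np.abs(off)) < 1e-7
        if self.generalized:
            self.r_pow_sums_ = {n: float(np.sum(off**n)) for n in (2, 4, 6, 8, 10)}
        self._null = None
        self._interp = None

    def _stat_rows(self, P):  # noqa: D401 - subclass hook
        raise NotImplementedError

    def _indep_pvalue(self, stat: float) -> float:
        raise NotImplementedError

    def _null_bank(self):
        if self._null is None:
            sampler = MvnNullSampler(self.ld_.r, self.n_draws, self.seed)
            self._null = sampler.null_stats(
                lambda z: self._stat_rows(_sorted_p(z_to_p(z)))
            )
        return self._null

    def _transform_z(self, Z):
        return self._transform_p(z_to_p(Z))

    def _transform_p(self, P):
        Ps = _sorted_p(np.atleast_2d(P))
        stat = self._stat_rows(Ps)
        use_mc = self.generalized and not self.independent_
        if use_mc:
            p, se = mc_pvalue(self._null_bank(), stat)
            self._last_detail = {"path": "mvn-monte-carlo",
                                 "mc_se": float(se[0]), "n_draws": self.n_draws}
        else:
            if Ps.shape[0] > 8:
                p = self._interp_pvalues(stat)
                self._last_detail = {"path": "crossing-grid"}
            else:
                p = np.array([self._indep_pvalue(s) for s in stat])
                self._last_detail = {"path": "crossing"}
        return stat, np.clip(p, _TINY, 1.0)

    def transform_pvalues(self, P):
        P = np.atleast_2d(np.asarray(P, dtype=float))
        s, p = self._transform_p(P)
        return np.column_stack([s, p])

    def _interp_pvalues(self, stat):
        """Monotone stat->p interpolation from exact crossing evaluations;
        used for large batches under the independence null."""
        from scipy.interpolate import PchipInterpolator

        lo, hi = np.min(stat), np.max(stat)
        if self._interp is None or lo < self._grid_lo or hi > self._grid_hi:
            glo, ghi = min(lo, 0.0), max(hi, 1.0) * 1.01 + 1e-6
            grid = np.linspace(glo, ghi, 48)
            pv = np.array([self._indep_pvalue(g) for g in grid])
            lp = np.minimum.accumulate(np.log(pv))
            keep = np.concatenate([[True], np.diff(lp) < -1e-14])
            self._interp = PchipInterpolator(grid[keep], lp[keep], extrapolate=True)
            self._grid_lo, self._grid_hi = glo, ghi
        return np.exp(self._interp(stat))


class HcTest(_ScanTestBase):
    """Higher criticism with the analytic independence-null p-value."""

    method = "HC"
    requires_ld = False
    generalized = False

    def _prepare(self):
        if self.ld_ is None:
            self.independent_ = True
            self._null = None
            self._interp = None
        else:
            super()._prepare()

    def _stat_rows(self, Ps):
        return hc_stat_rows(Ps)

    def _indep_pvalue(self, stat):
        m = self.m_ if self.m_ is not None else self._m_from_data
        return hc_crossing_pvalue(m, stat)

    def _transform_p(self, P):
        self._m_from_data = np.atleast_2d(P).shape[1]
        return super()._transform_p(P)


class BjTest(HcTest):
    """Berk-Jones with the analytic independence-null p-value."""

    method = "BJ"

    def _stat_rows(self, Ps):
        return bj_stat_rows(Ps)

    def _indep_pvalue(self, stat):
        m = self.m_ if self.m_ is not None else self._m_from_data
        return bj_crossing_pvalue(m, stat)


class GhcTest(_ScanTestBase):
    """Generalised higher criticism: exceedance counts standardised by their
    LD-adjusted variance.  Identical to HC when R = I."""

    method = "GHC"
    generalized = True

    def _stat_rows(self, Ps):
        b, m = Ps.shape
        j = np.arange(1, m + 1)
        t = stats.norm.isf(Ps / 2.0)
        var = exceedance_variance(t, m, self.r_pow_sums_)
        var = np.maximum(var, 1e-12)
        vals = (j[None, :] - m * Ps) / np.sqrt(var)
        allowed = Ps > 1.0 / m
        masked = np.where(allowed, vals, -np.inf)
        out = masked.max(axis=1)
        empty = ~allowed.any(axis=1)
        if np.any(empty):
            out[empty] = vals[empty].max(axis=1)
        return out

    def _indep_pvalue(self, stat):
        return hc_crossing_pvalue(self.m_, stat)


class GbjTest(_ScanTestBase):
    """Generalised Berk-Jones: the BJ exceedance log-likelihood ratio scaled
    by the LD-driven overdispersion of the exceedance count.  Identical to
    BJ when R = I."""

    method = "GBJ"
    generalized = True

    def _stat_rows(self, Ps):
        b, m = Ps.shape
        t = np.arange(1, m + 1) / m
        kl = m * _bj_kl(t[None, :], Ps)
        z = stats.norm.isf(Ps / 2.0)
        var = exceedance_variance(z, m, self.r_pow_sums_)
        v = np.maximum(var, 1e-12) / np.maximum(m * Ps * (1.0 - Ps), 1e-300)
        vals = kl / np.maximum(v, 1e-12)
        masked = np.where(Ps < t[None, :], vals, -np.inf)
        return np.maximum(masked.max(axis=1), 0.0)

    def _indep_pvalue(self, stat):
        return bj_crossing_pvalue(self.m_, stat)


class MinPTest(BaseSetTest):
    """Minimum-p test with the LD-adjusted multiplicity correction
    P(min p <= observed) evaluated on the MVN rectangle."""

    method = "minP"

    def __init__(self, delta=0.95, n_draws=100_000, seed=1234, mc_batch=True):
        self.delta = delta
        self.n_draws = n_draws
        self.seed = seed
        self.mc_batch = mc_batch

    def _prepare(self):
        self._null = None

    def _rect_pvalue(self, minp: float) -> float:
        c = stats.norm.isf(minp / 2.0)
        m = self.m_
        inside = float(
            stats.multivariate_normal.cdf(
                np.full(m, c), mean=np.zeros(m), cov=self.ld_.r,
                allow_singular=True, lower_limit=np.full(m, -c),
                abseps=1e-4, releps=0.0, maxpts=256_000,
            )
        )
        return min(max(1.0 - inside, _TINY), 1.0)

    def _null_minp(self):
        if self._null is None:
            sampler = MvnNullSampler(self.ld_.r, self.n_draws, self.seed)
            self._null = sampler.null_stats(
                lambda z: -z_to_p(z).min(axis=1)  # negated: larger = more extreme
            )
        return self._null

    def _transform_z(self, Z):
        return self._transform_p(z_to_p(Z))

    def _transform_p(self, P):
        P = np.atleast_2d(P)
        minp = clip_pvalues(P).min(axis=1)
        if P.shape[0] > 4 and self.mc_batch:
            p, se = mc_pvalue(self._null_minp(), -minp)
            self._last_detail = {"path": "mvn-bank", "mc_se": float(se[0])}
        else:
            p = np.array([self._rect_pvalue(x) for x in minp])
            self._last_detail = {"path": "mvn-rectangle"}
        return minp, np.clip(p, _TINY, 1.0)

    def transform_pvalues(self, P):
        s, p = self._transform_p(np.asarray(P, dtype=float))
        return np.column_stack([s, p])


# GATES p-value correlation approximation (polynomial in the genotype
# correlation, from the extended-Simes literature)
_GATES_COEF = (0.2982, -0.0127, 0.0588, 0.0099, 0.6281, -0.0009)


def pvalue_correlation(r: np.ndarray) -> np.ndarray:
    c6, c5, c4, c3, c2, c1 = _GATES_COEF
    out = (
        c6 * r**6 + c5 * r**5 + c4 * r**4 + c3 * r**3 + c2 * r**2 + c1 * r
    )
    np.fill_diagonal(out, 1.0)
    return out


def effective_number(eigvals: np.ndarray) -> float:
    """m_e = M - sum_{lambda_i > 1} (lambda_i - 1)."""
    lam = np.asarray(eigvals, dtype=float)
    return float(lam.size - np.sum(np.where(lam > 1.0, lam - 1.0, 0.0)))


class GatesTest(BaseSetTest):
    """Extended Simes procedure with the effective number of independent
    p-values estimated from the p-value correlation matrix."""

    method = "GATES"

    def __init__(self, delta=0.95):
        self.delta = delta

    def _prepare(self):
        self.rp_ = pvalue_correlation(self.ld_.r)
        self.me_full_ = effective_number(np.linalg.eigvalsh(self.rp_))

    def _transform_z(self, Z):
        return self._transform_p(z_to_p(Z))

    def _transform_p(self, P):
        P = np.atleast_2d(clip_pvalues(np.asarray(P, dtype=float)))
        b, m = P.shape
        out = np.empty(b)
        for i in range(b):
            order = np.argsort(P[i], kind="stable")
            ps = P[i][order]
            sub = self.rp_[np.ix_(order, order)]
            best = np.inf
            for j in range(1, m + 1):
                # me(j) <= j, so this term cannot beat the current minimum
                # unless the cheap bound does
                if self.me_full_ * ps[j - 1] / j >= best:
                    continue
                me_j = effective_number(np.linalg.eigvalsh(sub[:j, :j]))
                best = min(best, self.me_full_ * ps[j - 1] / me_j)
            out[i] = min(best, 1.0)
        self._last_detail = {"m_e": self.me_full_}
        return out, np.clip(out, _TINY, 1.0)

    def transform_pvalues(self, P):
        s, p = self._transform_p(P)
        return np.column_stack([s, p])


class SimpleMTest(BaseSetTest):
    """Bonferroni with the effective number of tests from the eigenvalue
    spectrum of R (top eigenvalues explaining 99.5% of the trace)."""

    method = "SimpleM"

    def __init__(self, delta=0.95, var_explained=0.995):
        self.delta = delta
        self.var_explained = var_explained

    def _prepare(self):
        lam = np.sort(np.linalg.eigvalsh(self.ld_.r))[::-1]
        cum = np.cumsum(lam)
        target = self.var_explained * lam.sum() - 1e-9  # guard float ties
        self.m_eff_ = int(np.searchsorted(cum, target) + 1)

    def _transform_z(self, Z):
        return self._transform_p(z_to_p(Z))

    def _transform_p(self, P):
        P = np.atleast_2d(P)
        minp = clip_pvalues(P).min(axis=1)
        p = np.minimum(1.0, self.m_eff_ * minp)
        self._last_detail = {"m_eff": self.m_eff_}
        return minp, np.maximum(p, _TINY)

    def transform_pvalues(self, P):
        s, p = self._transform_p(np.asarray(P, dtype=float))
        return np.column_stack([s, p])


# -- module-level operations -------------------------------------------------

def hc_stat(p_sorted):
    return float(hc_stat_rows(np.atleast_2d(np.asarray(p_sorted, float)))[0])


def hc_test(ss):
    return HcTest().fit(None).test(ss)


def bj_test(ss):
    return BjTest().fit(None).test(ss)


def ghc_test(ss, ld):
    return GhcTest().fit(ld).test(ss)


def gbj_test(ss, ld):
    return GbjTest().fit(ld).test(ss)


def minp_test(ss, ld):
    return MinPTest().fit(ld).test(ss)


def gates_test(ss, ld):
    return GatesTest().fit(ld).test(ss)


def simplem_test(ss, ld):
    return SimpleMTest().fit(ld).test(ss)
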