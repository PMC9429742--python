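"""Synthetic-data engine for the three benchmark designs.

Real genotype panels used in the original benchmark studies (GWAS cohorts,
biobank exomes, eQTL panels) are access-restricted, so genotypes are
simulated from a latent-Gaussian threshold model: within blocks of
consecutive SNPs the latent variables follow an AR(1) process (default
block 25, correlation 0.9, i.e. strong local LD), each of two allele copies
is thresholded at the inverse-normal of the target allele frequency, and
dosages are their sum — Hardy-Weinberg by construction, with block-wise LD
decaying by distance.  Reference and GWAS panels are drawn independently
from the same process, mirroring the reference-panel mismatch that LD-aware
tests face in practice.

Phenotypes follow Y = G beta + eps with effect architectures:

* sparse     — a random fraction ``prop_causal`` of SNPs has effects from the
               chosen distribution, the rest are zero;
* polygenic  — every SNP has an effect from the chosen distribution
               (normal, double exponential, or t with 4 df);
* mixed      — every SNP has a small normal effect and a random fraction
               receives an additional normal increment.

Effects and noise are rescaled so that the realised proportion of variance
explained, PVE = var(G beta) / (var(G beta) + var(eps)), matches the
requested value exactly.  The two-stage TWAS design simulates expression on
an eQTL panel (polygenic, PVE 5% by default), estimates joint eQTL weights
by maximum likelihood under a normal random-effects model (PX-EM), and
feeds the induced GWAS summary statistics plus estimated weights downstream,
optionally with horizontal pleiotropy (direct SNP effects with variance
0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .datatypes import GenotypePanel, SummaryStats, z_to_p


@dataclass
class TwasScenario:
    theta: float = 0.2
    pleiotropy_var: float = 0.0
    pve_expr: float = 0.05
    n_eqtl: int = 465


@dataclass
class SimulationScenario:
    architecture: str = "sparse"  # sparse | polygenic | mixed
    effect_dist: str = "normal"  # normal | double_exponential | t
    prop_causal: float = 0.2
    pve: float = 0.005
    m: int = 200
    n: int = 4901
    n_ref: int = 503
    maf_range: tuple = (0.05, 0.5)
    ld_block: int = 25
    ld_rho: float = 0.9
    t_df: float = 4.0
    same_direction: bool = False
    twas: Optional[TwasScenario] = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.pve < 1.0):
            raise ValueError("pve must lie in (0, 1)")
        if not (0.0 < self.prop_causal <= 1.0):
            raise ValueError("prop_causal must lie in (0, 1]")


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _latent_ar1(rng, n, m, block, rho):
    eps = rng.standard_normal((n, m))
    x = np.empty_like(eps)
    scale = np.sqrt(1.0 - rho**2)
    for j in range(m):
        if j % block == 0:
            x[:, j] = eps[:, j]
        else:
            x[:, j] = rho * x[:, j - 1] + scale * eps[:, j]
    return x


def simulate_genotypes(
    n: int,
    m: int,
    maf_range=(0.05, 0.5),
    block: int = 25,
    rho: float = 0.9,
    seed=0,
    spacing_bp: int = 1000,
) -> GenotypePanel:
    """Latent-Gaussian AR(1)-block genotypes with HWE dosages.

    Columns whose realised MAF falls outside ``maf_range`` are redrawn (with
    targets resampled from the central part of the range) so the returned
    panel honours the requested frequency window; no SNP is monomorphic.
    """
    lo, hi = maf_range
    if not (0.0 < lo < hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    if block < 1:
        raise ValueError("block must be >= 1")
    rng = _rng(seed)
    target = rng.uniform(lo, hi, size=m)
    thresh = stats.norm.ppf(target)
    a1 = _latent_ar1(rng, n, m, block, rho) < thresh
    a2 = _latent_ar1(rng, n, m, block, rho) < thresh
    g = (a1.astype(np.int8) + a2.astype(np.int8)).astype(float)

    from .datatypes import compute_maf

    for _ in range(20):
        maf = compute_maf(g)
        bad = (maf < lo) | (maf >= hi) | (maf <= 0)
        if not bad.any():
            break
        # redraw offending columns with targets pulled toward mid-range
        nb = int(bad.sum())
        t2 = rng.uniform(lo + 0.25 * (hi - lo), lo + 0.75 * (hi - lo), size=nb)
        th2 = stats.norm.ppf(t2)
        b1 = rng.standard_normal((n, nb)) < th2
        b2 = rng.standard_normal((n, nb)) < th2
        g[:, bad] = (b1.astype(np.int8) + b2.astype(np.int8)).astype(float)
    positions = spacing_bp * np.arange(1, m + 1, dtype=np.int64)
    snp_ids = np.array([f"snp{i+1}" for i in range(m)])
    return GenotypePanel(matrix=g, snp_ids=snp_ids, positions=positions,
                         chrom=np.array(["1"] * m))


def simulate_effects(scenario: SimulationScenario, rng=None) -> np.ndarray:
    """Per-SNP effect sizes under the scenario's architecture."""
    rng = _rng(scenario.seed if rng is None else rng)
    m = scenario.m

    def draw(size):
        d = scenario.effect_dist
        if d == "normal":
            return rng.standard_normal(size)
        if d == "double_exponential":
            return rng.laplace(0.0, 1.0, size)
        if d == "t":
            return rng.standard_t(scenario.t_df, size)
        raise ValueError(f"unknown effect distribution {d!r}")

    arch = scenario.architecture
    if arch == "sparse":
        beta = np.zeros(m)
        n_causal = int(round(scenario.prop_causal * m))
        n_causal = max(n_causal, 1)
        idx = rng.choice(m, size=n_causal, replace=False)
        beta[idx] = draw(n_causal)
    elif arch == "polygenic":
        beta = draw(m)
    elif arch == "mixed":
        beta = rng.standard_normal(m)
        n_extra = max(int(round(scenario.prop_causal * m)), 1)
        idx = rng.choice(m, size=n_extra, replace=False)
        beta[idx] += rng.standard_normal(n_extra)
    else:
        raise ValueError(f"unknown architecture {arch!r}")
    if scenario.same_direction:
        beta = np.abs(beta)
    return beta


def simulate_phenotype(G: np.ndarray, beta: np.ndarray, pve: float, seed=0) -> np.ndarray:
    """Phenotype with the realised PVE equal to ``pve`` (to 1e-6).

    With beta identically zero (the null design), returns pure standard
    normal noise.
    """
    rng = _rng(seed)
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if beta is None or not np.any(beta):
        return rng.standard_normal(n)
    if not (0.0 < pve < 1.0):
        raise ValueError("pve must lie in (0, 1)")
    g = G @ beta
    var_g = g.var()
    if var_g <= 0:
        return rng.standard_normal(n)
    eps = rng.standard_normal(n)
    eps = eps - eps.mean()
    target_var_eps = var_g * (1.0 - pve) / pve
    eps *= np.sqrt(target_var_eps / eps.var())
    return g + eps


def realized_pve(G, beta, y) -> float:
    g = np.asarray(G) @ np.asarray(beta)
    var_g = g.var()
    var_e = (y - g).var()
    return float(var_g / (var_g + var_e))


def _marginal_z_matrix(G_std: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """t-statistics (slope/SE) of per-SNP simple regressions, for one or
    many phenotype columns.  G_std must be column-standardised; Y is
    (n,) or (n, B)."""
    n = G_std.shape[0]
    Yc = Y - Y.mean(axis=0, keepdims=True) if Y.ndim == 2 else Y - Y.mean()
    sdY = Yc.std(axis=0, ddof=1) if Y.ndim == 2 else Yc.std(ddof=1)
    r = (G_std.T @ Yc) / ((n - 1) * sdY)
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    return r * np.sqrt((n - 2) / (1.0 - r**2))


def marginal_gwas(G, Y, snp_ids=None, maf=None) -> SummaryStats:
    """Single-marker linear-regression scan.

    z is the slope/SE t-statistic and p its two-sided normal tail
    (the large-n convention p = 2 Phi(-|z|)).  Monomorphic SNPs are
    excluded with a warning.
    """
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, m = G.shape
    if n <= 2:
        raise ValueError("need more than 2 individuals")
    sd = G.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} monomorphic SNPs")
    Gs = (G[:, keep] - G[:, keep].mean(axis=0)) / sd[keep]
    z = _marginal_z_matrix(Gs, Y)
    if snp_ids is None:
        snp_ids = np.array([f"snp{i+1}" for i in range(m)])
    return SummaryStats(
        snp_ids=np.asarray(snp_ids)[keep],
        z=z,
        p=np.maximum(z_to_p(z), np.finfo(float).tiny),
        n=n,
        maf=None if maf is None else np.asarray(maf)[keep],
    )


def marginal_gwas_many(G, Y_matrix) -> np.ndarray:
    """Z-score matrix (B, M) for B phenotype replicates on one panel."""
    G = np.asarray(G, dtype=float)
    sd = G.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("monomorphic SNP in panel")
    Gs = (G - G.mean(axis=0)) / sd
    return _marginal_z_matrix(Gs, np.asarray(Y_matrix, dtype=float)).T


# ---------------------------------------------------------------------------
# TWAS stage one: random-effects eQTL weights via PX-EM maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class TwasStageOne:
    w_hat: np.ndarray
    expression: np.ndarray
    w_true: Optional[np.ndarray] = None
    sigma2_w: float = np.nan
    sigma2_e: float = np.nan
    n_iter: int = 0


def estimate_eqtl_weights(
    G1, e, tol: float = 1e-6, max_iter: int = 1000
) -> TwasStageOne:
    """Joint eQTL effects under e = G1 w + eps, w ~ N(0, s2w I).

    Variance components are estimated by PX-EM maximum likelihood; the
    returned weights are the posterior means E[w | e] at the fitted
    variances.  With noiseless expression the fit approaches the
    least-squares solution and recovers w exactly.
    """
    G = np.asarray(G1, dtype=float)
    e = np.asarray(e, dtype=float).ravel()
    n, m = G.shape
    if e.shape[0] != n:
        raise ValueError("expression length must match panel rows")
    gtg = G.T @ G
    d, V = np.linalg.eigh(gtg)
    d = np.clip(d, 0.0, None)
    gte = G.T @ e
    b = V.T @ gte  # rotated G'e
    ee = float(e @ e)

    s2w = max(float(np.var(e)) / max(m, 1), 1e-8)
    s2e = max(float(np.var(e)), 1e-8)
    it = 0
    for it in range(1, max_iter + 1):
        # posterior in the eigenbasis
        prec = d / s2e + 1.0 / s2w
        mu_rot = (b / s2e) / prec
        var_rot = 1.0 / prec
        # sufficient statistics
        e_ww = float(mu_rot @ mu_rot + var_rot.sum())
        e_wgg = float(d @ (mu_rot**2 + var_rot))
        e_gmu = float(b @ mu_rot)
        # PX-EM: expansion factor absorbed into the weight scale
        alpha = e_gmu / e_wgg if e_wgg > 0 else 1.0
        s2e_new = max((ee - 2.0 * alpha * e_gmu + alpha**2 * e_wgg) / n, 1e-12)
        s2w_new = max(alpha**2 * e_ww / m, 1e-12)
        delta = abs(s2e_new - s2e) + abs(s2w_new - s2w)
        s2e, s2w = s2e_new, s2w_new
        if delta < tol * (s2e + s2w):
            break
    else:
        raise RuntimeError(
            f"PX-EM did not converge in {max_iter} iterations "
            f"(s2w={s2w:.3e}, s2e={s2e:.3e})"
        )
    prec = d / s2e + 1.0 / s2w
    w_hat = V @ ((b / s2e) / prec)
    return TwasStageOne(w_hat=w_hat, expression=e, sigma2_w=s2w,
                        sigma2_e=s2e, n_iter=it)


def simulate_twas(scenario: SimulationScenario, seed=None):
    """Two-stage TWAS simulation.

    Stage 1 draws an eQTL panel, polygenic true weights and expression at
    ``pve_expr``; stage 2 generates the GWAS phenotype
    Y = (G2 w_true) * theta + G2 b + eps with optional pleiotropic direct
    effects b ~ N(0, pleiotropy_var), then runs the marginal GWAS.

    Returns (TwasStageOne, SummaryStats, GenotypePanel reference panel).
    """
    tw = scenario.twas or TwasScenario()
    rng = _rng(scenario.seed if seed is None else seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)

    panel_e = simulate_genotypes(
        tw.n_eqtl, scenario.m, scenario.maf_range, scenario.ld_block,
        scenario.ld_rho, seed=seeds[0],
    )
    sc1 = SimulationScenario(
        architecture="polygenic", effect_dist="normal", pve=tw.pve_expr,
        m=scenario.m, seed=int(seeds[1]),
    )
    w_true = simulate_effects(sc1, rng=np.random.default_rng(int(seeds[1])))
    # scale so the expression variance explained is pve_expr against unit
    # residual noise; stage two inherits the same weight scale
    gvar = (panel_e.matrix @ w_true).var()
    w_true = w_true * np.sqrt(tw.pve_expr / (1.0 - tw.pve_expr) / gvar)
    expr = simulate_phenotype(panel_e.matrix, w_true, tw.pve_expr, seed=int(seeds[2]))
    stage1 = estimate_eqtl_weights(panel_e.matrix, expr)
    stage1.w_true = w_true

    panel_g = simulate_genotypes(
        scenario.n, scenario.m, scenario.maf_range, scenario.ld_block,
        scenario.ld_rho, seed=seeds[3],
    )
    rng2 = np.random.default_rng(int(seeds[4]))
    y = (panel_g.matrix @ w_true) * tw.theta
    if tw.pleiotropy_var > 0:
        bdir = rng2.normal(0.0, np.sqrt(tw.pleiotropy_var), size=scenario.m)
        y = y + panel_g.matrix @ bdir
    y = y + rng2.standard_normal(scenario.n)
    ss = marginal_gwas(panel_g.matrix, y, snp_ids=panel_g.snp_ids,
                       maf=panel_g.maf)
    panel_ref = simulate_genotypes(
        scenario.n_ref, scenario.m, scenario.maf_range, scenario.ld_block,
        scenario.ld_rho, seed=seeds[5],
    )
    return stage1, ss, panel_ref
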