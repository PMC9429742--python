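"""Benchmark harness: type-I-error calibration, power, ranking and the
per-gene scan driver.

The calibration suite mirrors the benchmark design: one simulated GWAS
panel and one independent reference panel share an LD process; B null
phenotypes (beta = 0) are drawn, a marginal GWAS is run for each, and every
requested SNP-set method maps the resulting Z-score rows to p-values.  The
empirical type-I-error ratio (rate / alpha), averaged over
alpha in {0.05, 0.01, 0.001}, classifies each method as inflated
(ratio > 1.2), well-controlled (0.8 <= ratio <= 1.2) or conservative
(ratio < 0.8).
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import SummaryStats, z_to_p
from .ld import reference_ld
from .pcomb import (AcatTest, ArtATest, ArtTest, FisherTest, GmTest, HmpTest,
                    RtpTest, SimesTest, TpmTest)
from .quad import (BurdenTest, DotTest, FlmTest, MlrTest, SkatOTest, SkatTest)
from .rank import (BjTest, GatesTest, GbjTest, GhcTest, HcTest, MinPTest,
                   SimpleMTest)
from .simulate import (SimulationScenario, marginal_gwas_many,
                       simulate_effects, simulate_genotypes,
                       simulate_phenotype)
from .weights import maf_beta_weights, transform_eqtl_weights

logger = logging.getLogger("snpset")

ALL_METHODS = (
    "MLR", "FLM", "HC", "GHC", "BJ", "GBJ", "DOT", "BT", "SKATO", "SKAT",
    "Simes", "FCP", "TPM", "RTP", "minP", "ART", "ART-A", "GM", "SimpleM",
    "GATES", "HMP", "ACAT",
)

CALIBRATED_SEVEN = ("BT", "SKATO", "SKAT", "Simes", "minP", "HMP", "ACAT")

# methods that accept a per-SNP weight vector directly in the statistic
WEIGHTED_METHODS = ("BT", "SKAT", "SKATO", "ACAT", "HMP")


def make_estimator(name: str, n: Optional[int] = None, positions=None,
                   weights=None, delta: float = 0.95, seed: int = 1234,
                   n_draws: int = 100_000):
    """Instantiate one of the 22 SNP-set tests by its benchmark name."""
    key = name.upper().replace("_", "-")
    if key == "MLR":
        return MlrTest(delta=delta, n=n)
    if key == "FLM":
        return FlmTest(delta=delta, n=n, positions=positions)
    if key == "HC":
        return HcTest(delta=delta)
    if key == "GHC":
        return GhcTest(delta=delta, seed=seed, n_draws=n_draws)
    if key == "BJ":
        return BjTest(delta=delta)
    if key == "GBJ":
        return GbjTest(delta=delta, seed=seed, n_draws=n_draws)
    if key == "DOT":
        return DotTest(delta=delta)
    if key == "BT":
        return BurdenTest(delta=delta, weights=weights)
    if key == "SKATO":
        return SkatOTest(delta=delta, weights=weights)
    if key == "SKAT":
        return SkatTest(delta=delta, weights=weights)
    if key == "SIMES":
        return SimesTest()
    if key == "FCP":
        return FisherTest()
    if key == "TPM":
        return TpmTest()
    if key == "RTP":
        return RtpTest()
    if key == "MINP":
        return MinPTest(delta=delta, seed=seed, n_draws=n_draws)
    if key == "ART":
        return ArtTest()
    if key == "ART-A":
        return ArtATest(seed=seed)
    if key == "GM":
        return GmTest()
    if key == "SIMPLEM":
        return SimpleMTest(delta=delta)
    if key == "GATES":
        return GatesTest(delta=delta)
    if key == "HMP":
        return HmpTest(weights=weights)
    if key == "ACAT":
        return AcatTest(weights=weights)
    raise ValueError(f"unknown method {name!r}")


# ---------------------------------------------------------------------------
# elementary report operations
# ---------------------------------------------------------------------------

def type1_ratio(pvalues, alpha: float):
    """(empirical rate at alpha) / alpha, with its Monte-Carlo SE."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if p.size < 1.0 / alpha:
        warnings.warn(
            f"only {p.size} replicates for alpha={alpha}; ratio is noisy"
        )
    rate = float(np.mean(p <= alpha))
    se = np.sqrt(rate * (1.0 - rate) / p.size) / alpha
    return rate / alpha, se


def classify_calibration(avg_ratio: float) -> str:
    if avg_ratio < 0:
        raise ValueError("ratio must be nonnegative")
    if avg_ratio > 1.2:
        return "inflated"
    if avg_ratio < 0.8:
        return "conservative"
    return "well-controlled"


def power(pvalues, alpha: float = 1e-5):
    """Proportion of p-values below alpha, with binomial SE."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    pw = float(np.mean(p < alpha))
    return pw, np.sqrt(pw * (1.0 - pw) / p.size)


def rank_methods(power_table: pd.DataFrame) -> pd.Series:
    """Average dense rank (1 = most powerful) across scenarios.

    ``power_table``: rows = scenarios, columns = methods, entries = power.
    Ties share the mean rank; ranks are invariant to monotone rescaling."""
    if power_table.shape[0] < 2:
        raise ValueError("need at least two scenarios to rank")
    ranks = power_table.rank(axis=1, ascending=False, method="average")
    return ranks.mean(axis=0).sort_values()


# ---------------------------------------------------------------------------
# calibration and power suites
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    table: pd.DataFrame  # per-method rows: rate/ratio per alpha, average, label
    b_reps: int
    alphas: tuple
    scenario: SimulationScenario

    def label(self, method: str) -> str:
        return self.table.loc[method, "label"]

    def n_well_controlled(self) -> int:
        return int((self.table["label"] == "well-controlled").sum())


@dataclass
class PowerReport:
    table: pd.DataFrame  # per-method: power, se
    alpha: float
    b_reps: int
    scenario: SimulationScenario


def _child_seeds(seed: int, k: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, k)]


def _simulation_weights(scenario: SimulationScenario, panel, mode):
    if mode is None:
        return {}
    if mode == "maf_beta":
        wv = maf_beta_weights(np.clip(panel.maf, 1e-6, 0.5))
        return {m: wv.w for m in ("BT", "SKAT", "SKATO")}
    raise ValueError(f"unknown weight mode {mode!r}")


def _weights_for(method, wmap):
    return wmap.get(method.upper().replace("_", "-"))


def null_z_scores(scenario: SimulationScenario, b_reps: int, seed: int,
                  chunk: int = 2000):
    """Simulate the scenario's panels and B null-phenotype marginal GWAS
    Z-score rows.  Returns (Z, gwas_panel, reference_panel)."""
    s_panel, s_ref, s_y = _child_seeds(seed, 3)
    panel = simulate_genotypes(scenario.n, scenario.m, scenario.maf_range,
                               scenario.ld_block, scenario.ld_rho, seed=s_panel)
    ref = simulate_genotypes(scenario.n_ref, scenario.m, scenario.maf_range,
                             scenario.ld_block, scenario.ld_rho, seed=s_ref)
    rng = np.random.default_rng(s_y)
    zs = []
    left = b_reps
    while left > 0:
        nb = min(chunk, left)
        y = rng.standard_normal((scenario.n, nb))
        zs.append(marginal_gwas_many(panel.matrix, y))
        left -= nb
    return np.vstack(zs), panel, ref


def effect_z_scores(scenario: SimulationScenario, b_reps: int, seed: int,
                    chunk: int = 500):
    """B replicates with freshly drawn effects per replicate."""
    s_panel, s_ref, s_eff = _child_seeds(seed, 3)
    panel = simulate_genotypes(scenario.n, scenario.m, scenario.maf_range,
                               scenario.ld_block, scenario.ld_rho, seed=s_panel)
    ref = simulate_genotypes(scenario.n_ref, scenario.m, scenario.maf_range,
                             scenario.ld_block, scenario.ld_rho, seed=s_ref)
    rng = np.random.default_rng(s_eff)
    zs = []
    for start in range(0, b_reps, chunk):
        nb = min(chunk, b_reps - start)
        Y = np.empty((scenario.n, nb))
        for i in range(nb):
            beta = simulate_effects(scenario, rng=rng)
            Y[:, i] = simulate_phenotype(panel.matrix, beta, scenario.pve,
                                         seed=rng)
        zs.append(marginal_gwas_many(panel.matrix, Y))
    return np.vstack(zs), panel, ref


def run_methods_on_z(Z, ref_panel, methods=ALL_METHODS, n=None,
                     positions=None, wmap=None, delta=0.95, seed=1234,
                     max_fail_frac=0.01) -> pd.DataFrame:
    """Fit each method on the reference panel and map all Z rows to
    p-values.  Returns a DataFrame (replicates x methods)."""
    wmap = wmap or {}
    ld = reference_ld(ref_panel.matrix, delta=delta)
    out = {}
    for name in methods:
        est = make_estimator(name, n=n, positions=positions,
                             weights=_weights_for(name, wmap), delta=delta,
                             seed=seed)
        t0 = time.time()
        try:
            est.fit(ld)
            out[name] = est.transform(Z)[:, 1]
        except Exception as exc:
            raise RuntimeError(f"method {name} failed: {exc}") from exc
        logger.info("%s: %d replicates in %.1fs", name, len(Z),
                    time.time() - t0)
    return pd.DataFrame(out)


def run_calibration_suite(
    methods=ALL_METHODS,
    scenario: Optional[SimulationScenario] = None,
    b_reps: int = 10_000,
    alphas=(0.05, 0.01, 0.001),
    seed: int = 0,
    weight_mode=None,
    delta: float = 0.95,
) -> CalibrationReport:
    """Type-I-error benchmark under the null (beta = 0)."""
    scenario = scenario or SimulationScenario()
    Z, panel, ref = null_z_scores(scenario, b_reps, seed)
    wmap = _simulation_weights(scenario, ref, weight_mode)
    pvals = run_methods_on_z(Z, ref, methods, n=scenario.n,
                             positions=ref.positions, wmap=wmap, delta=delta,
                             seed=_child_seeds(seed, 4)[3])
    rows = []
    for name in pvals.columns:
        entry = {"method": name}
        ratios = []
        for a in alphas:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ratio, se = type1_ratio(pvals[name], a)
            entry[f"ratio_{a:g}"] = ratio
            entry[f"se_{a:g}"] = se
            ratios.append(ratio)
        entry["average"] = float(np.mean(ratios))
        entry["label"] = classify_calibration(entry["average"])
        rows.append(entry)
    table = pd.DataFrame(rows).set_index("method")
    return CalibrationReport(table=table, b_reps=b_reps, alphas=tuple(alphas),
                             scenario=scenario)


def run_power_suite(
    methods=CALIBRATED_SEVEN,
    scenario: Optional[SimulationScenario] = None,
    b_reps: int = 1000,
    alpha: float = 1e-5,
    seed: int = 0,
    weight_mode=None,
    delta: float = 0.95,
) -> PowerReport:
    """Power benchmark with per-replicate effect draws."""
    scenario = scenario or SimulationScenario()
    Z, panel, ref = effect_z_scores(scenario, b_reps, seed)
    wmap = _simulation_weights(scenario, ref, weight_mode)
    pvals = run_methods_on_z(Z, ref, methods, n=scenario.n,
                             positions=ref.positions, wmap=wmap, delta=delta,
                             seed=_child_seeds(seed, 4)[3])
    rows = []
    for name in pvals.columns:
        pw, se = power(pvals[name], alpha)
        rows.append({"method": name, "power": pw, "se": se})
    table = pd.DataFrame(rows).set_index("method")
    return PowerReport(table=table, alpha=alpha, b_reps=b_reps,
                       scenario=scenario)


def run_twas_power(
    methods=("BT", "SKAT", "SKATO", "HMP", "ACAT"),
    scenario: Optional[SimulationScenario] = None,
    b_reps: int = 500,
    alpha: float = 1e-3,
    seed: int = 0,
    delta: float = 0.95,
) -> PowerReport:
    """Two-stage TWAS power: per replicate, re-estimate eQTL weights and run
    the weighted tests on the stage-two summary statistics."""
    from .datatypes import SummaryStats, z_to_p
    from .simulate import (TwasScenario, estimate_eqtl_weights,
                           marginal_gwas_many, simulate_phenotype)

    scenario = scenario or SimulationScenario(n=2000, m=100)
    tw = scenario.twas or TwasScenario()
    m = scenario.m
    s_e, s_g, s_r, s_fx = _child_seeds(seed, 4)
    # panels are fixed across replicates, as in the benchmark design
    panel_e = simulate_genotypes(tw.n_eqtl, m, scenario.maf_range,
                                 scenario.ld_block, scenario.ld_rho, seed=s_e)
    panel_g = simulate_genotypes(scenario.n, m, scenario.maf_range,
                                 scenario.ld_block, scenario.ld_rho, seed=s_g)
    panel_r = simulate_genotypes(scenario.n_ref, m, scenario.maf_range,
                                 scenario.ld_block, scenario.ld_rho, seed=s_r)
    ld = reference_ld(panel_r.matrix, delta=delta)
    rng = np.random.default_rng(s_fx)
    pvals = {name: [] for name in methods}
    tiny = np.finfo(float).tiny
    for rep in range(b_reps):
        w_true = rng.standard_normal(m)
        # scale joint eQTL effects so expression variance explained is
        # pve_expr against unit residual noise; the same (small) weights
        # then drive the stage-two genetic signal through theta
        gvar = (panel_e.matrix @ w_true).var()
        w_true *= np.sqrt(tw.pve_expr / (1.0 - tw.pve_expr) / gvar)
        expr = simulate_phenotype(panel_e.matrix, w_true, tw.pve_expr, seed=rng)
        stage1 = estimate_eqtl_weights(panel_e.matrix, expr)
        y = (panel_g.matrix @ w_true) * tw.theta
        if tw.pleiotropy_var > 0:
            bdir = rng.normal(0.0, np.sqrt(tw.pleiotropy_var), size=m)
            y = y + panel_g.matrix @ bdir
        y = y + rng.standard_normal(scenario.n)
        z = marginal_gwas_many(panel_g.matrix, y[:, None])[0]
        ss = SummaryStats(snp_ids=panel_g.snp_ids, z=z,
                          p=np.maximum(z_to_p(z), tiny), n=scenario.n)
        for name in methods:
            wv = transform_eqtl_weights(stage1.w_hat, name)
            est = make_estimator(name, n=scenario.n, weights=wv.w,
                                 delta=delta, seed=seed)
            pvals[name].append(est.fit(ld).test(ss).p)
    rows = []
    for name in methods:
        pw, se = power(np.array(pvals[name]), alpha)
        rows.append({"method": name, "power": pw, "se": se})
    table = pd.DataFrame(rows).set_index("method")
    return PowerReport(table=table, alpha=alpha, b_reps=b_reps,
                       scenario=scenario)


# ---------------------------------------------------------------------------
# per-gene scan
# ---------------------------------------------------------------------------

GENOME_WIDE_P = 5e-8


def run_scan(
    sumstats_path,
    annotation_path,
    reference_path,
    methods: Sequence[str] = CALIBRATED_SEVEN,
    weights_path=None,
    window_bp: int = 100_000,
    min_snps: int = 10,
    delta: float = 0.95,
    n: Optional[int] = None,
    seed: int = 1234,
    out_path=None,
) -> pd.DataFrame:
    """Gene-by-gene SNP-set scan from files.

    For each gene window: match SNPs between summary statistics and the
    reference panel, estimate shrunk LD, run the requested tests, and
    Bonferroni-adjust each method across genes.  A gene is flagged novel
    when none of its member SNPs reaches genome-wide significance
    (P < 5e-8) marginally.
    """
    from .io import build_snp_sets, read_annotation, read_genotypes, \
        read_sumstats, read_weight_file

    ss_all = read_sumstats(sumstats_path)
    panel = read_genotypes(reference_path)
    ann = read_annotation(annotation_path)
    sets = build_snp_sets(ann, panel, window_bp=window_bp, min_snps=min_snps)
    wtab = None
    if weights_path is not None:
        wtab = read_weight_file(weights_path).set_index("snp")["weight"]

    ss_index = {s: i for i, s in enumerate(ss_all.snp_ids)}
    rows = []
    for gs in sets:
        common = [s for s in gs.snp_ids if s in ss_index]
        if len(common) < min_snps:
            continue
        idx = np.array([ss_index[s] for s in common])
        z = ss_all.z[idx]
        sub = panel.subset(common)
        try:
            ld = reference_ld(sub.matrix, delta=delta)
        except ValueError as exc:
            logger.warning("gene %s skipped: %s", gs.gene_id, exc)
            continue
        row = {"gene": gs.gene_id, "M": len(common)}
        ss = SummaryStats(snp_ids=np.array(common), z=z, p=z_to_p(z),
                          n=n if n is not None else ss_all.n)
        for name in methods:
            w = None
            if wtab is not None and name.upper() in WEIGHTED_METHODS:
                raw = wtab.reindex(common).fillna(0.0).to_numpy()
                w = transform_eqtl_weights(raw, name).w if np.any(raw) else None
            est = make_estimator(name, n=ss.n, positions=sub.positions,
                                 weights=w, delta=delta, seed=seed)
            try:
                row[f"p_{name}"] = est.fit(ld).test(ss).p
            except Exception as exc:
                logger.warning("gene %s, method %s failed: %s",
                               gs.gene_id, name, exc)
                row[f"p_{name}"] = np.nan
        row["novel"] = bool(np.all(ss.p >= GENOME_WIDE_P))
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        n_genes = len(df)
        for name in methods:
            df[f"p_bonf_{name}"] = np.minimum(df[f"p_{name}"] * n_genes, 1.0)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df
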