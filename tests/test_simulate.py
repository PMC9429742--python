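"""Synthetic genotype / phenotype / TWAS simulation engine."""

import numpy as np
import pytest
from scipy import stats

from snpset.datatypes import z_to_p
from snpset.ld import empirical_ld
from snpset.simulate import (SimulationScenario, TwasScenario,
                             estimate_eqtl_weights, marginal_gwas,
                             marginal_gwas_many, realized_pve,
                             simulate_effects, simulate_genotypes,
                             simulate_phenotype, simulate_twas)


class TestGenotypes:
    def test_deterministic_given_seed(self):
        a = simulate_genotypes(200, 30, seed=42)
        b = simulate_genotypes(200, 30, seed=42)
        assert np.array_equal(a.matrix, b.matrix)

    def test_rare_mode_maf_bound(self):
        panel = simulate_genotypes(15_000, 100, maf_range=(0.001, 0.05), seed=2)
        assert np.all(panel.maf < 0.05)
        assert np.all(panel.maf > 0)

    def test_no_ld_when_rho_zero(self):
        panel = simulate_genotypes(10_000, 2, block=1, rho=0.0, seed=5)
        assert abs(empirical_ld(panel).r[0, 1]) < 0.05

    def test_block_ld_present(self):
        panel = simulate_genotypes(4000, 25, block=25, rho=0.9, seed=6)
        r = empirical_ld(panel).r
        adjacent = np.diag(r, 1).mean()
        assert adjacent > 0.4  # strong local LD (attenuated by thresholding)

    def test_bad_args(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 5, maf_range=(0.5, 0.1))
        with pytest.raises(ValueError):
            simulate_genotypes(10, 5, rho=1.0)


class TestEffects:
    def test_sparse_counts(self):
        sc = SimulationScenario(architecture="sparse", prop_causal=0.05, m=200,
                                seed=3)
        beta = simulate_effects(sc)
        assert (beta != 0).sum() == 10

    def test_polygenic_all_causal(self):
        sc = SimulationScenario(architecture="polygenic", m=100, seed=4)
        assert np.all(simulate_effects(sc) != 0)

    def test_same_direction(self):
        sc = SimulationScenario(architecture="sparse", prop_causal=0.5, m=50,
                                same_direction=True, seed=5)
        assert np.all(simulate_effects(sc) >= 0)

    @pytest.mark.parametrize("dist", ["normal", "double_exponential", "t"])
    def test_effect_distributions_run(self, dist):
        sc = SimulationScenario(architecture="polygenic", effect_dist=dist,
                                m=500, seed=6)
        beta = simulate_effects(sc)
        assert np.isfinite(beta).all()

    def test_mixed_architecture(self):
        sc = SimulationScenario(architecture="mixed", prop_causal=0.2, m=100,
                                seed=7)
        assert np.all(simulate_effects(sc) != 0)


class TestPhenotype:
    def test_realised_pve_exact(self, rng):
        panel = simulate_genotypes(1000, 20, seed=8)
        beta = rng.standard_normal(20)
        for pve in (0.003, 0.01, 0.3):
            y = simulate_phenotype(panel.matrix, beta, pve, seed=9)
            assert realized_pve(panel.matrix, _scaled(panel.matrix, beta, y),
                                y) == pytest.approx(pve, abs=1e-6)

    def test_null_mode(self):
        panel = simulate_genotypes(500, 10, seed=10)
        y = simulate_phenotype(panel.matrix, np.zeros(10), 0.5, seed=11)
        assert y.shape == (500,)
        assert abs(np.corrcoef(y, panel.matrix @ np.ones(10))[0, 1]) < 0.15

    def test_odds_double_with_pve(self):
        panel = simulate_genotypes(800, 15, seed=12)
        beta = np.ones(15)
        y1 = simulate_phenotype(panel.matrix, beta, 0.2, seed=13)
        y2 = simulate_phenotype(panel.matrix, beta, 1 / 3, seed=13)
        g = panel.matrix @ beta
        odds1 = g.var() / (y1 - g).var()
        odds2 = g.var() / (y2 - g).var()
        assert odds2 / odds1 == pytest.approx(2.0, rel=1e-6)


def _scaled(G, beta, y):
    # simulate_phenotype leaves beta unscaled and rescales noise; the
    # genetic component is G beta itself
    return beta


class TestMarginalGwas:
    def test_perfect_signal(self):
        panel = simulate_genotypes(300, 3, seed=14)
        y = panel.matrix[:, 0] + 1e-6 * np.random.default_rng(15).standard_normal(300)
        ss = marginal_gwas(panel.matrix, y)
        assert ss.p[0] < 1e-10

    def test_null_p_uniform(self):
        panel = simulate_genotypes(400, 1000, block=1, rho=0.0, seed=16)
        y = np.random.default_rng(17).standard_normal(400)
        ss = marginal_gwas(panel.matrix, y)
        assert stats.kstest(ss.p, "uniform").pvalue > 0.01

    def test_z_p_consistency(self):
        panel = simulate_genotypes(500, 20, seed=18)
        y = np.random.default_rng(19).standard_normal(500)
        ss = marginal_gwas(panel.matrix, y)
        assert np.max(np.abs(ss.p - z_to_p(ss.z))) < 1e-8

    def test_batch_matches_single(self):
        panel = simulate_genotypes(300, 10, seed=20)
        Y = np.random.default_rng(21).standard_normal((300, 3))
        Z = marginal_gwas_many(panel.matrix, Y)
        for j in range(3):
            ss = marginal_gwas(panel.matrix, Y[:, j])
            assert np.allclose(Z[j], ss.z, atol=1e-10)

    def test_monomorphic_excluded(self):
        g = np.column_stack([np.ones(50), np.arange(50) % 3]).astype(float)
        with pytest.warns(UserWarning, match="monomorphic"):
            ss = marginal_gwas(g, np.random.default_rng(22).standard_normal(50))
        assert ss.m == 1


class TestEqtlWeights:
    def test_noiseless_recovery(self):
        panel = simulate_genotypes(465, 200, seed=23)
        w = np.random.default_rng(24).standard_normal(200) * 0.1
        st = estimate_eqtl_weights(panel.matrix, panel.matrix @ w)
        assert np.corrcoef(st.w_hat, w)[0, 1] > 0.99

    def test_noise_shrinks_weights(self):
        panel = simulate_genotypes(465, 100, seed=25)
        rng = np.random.default_rng(26)
        w = rng.standard_normal(100) * 0.1
        e_signal = simulate_phenotype(panel.matrix, w, 0.3, seed=27)
        st_sig = estimate_eqtl_weights(panel.matrix, e_signal)
        st_noise = estimate_eqtl_weights(panel.matrix, rng.standard_normal(465))
        assert np.abs(st_noise.w_hat).mean() < np.abs(st_sig.w_hat).mean()

    def test_deterministic(self):
        panel = simulate_genotypes(200, 50, seed=28)
        e = simulate_phenotype(panel.matrix,
                               np.random.default_rng(29).standard_normal(50),
                               0.05, seed=30)
        a = estimate_eqtl_weights(panel.matrix, e).w_hat
        b = estimate_eqtl_weights(panel.matrix, e).w_hat
        assert np.array_equal(a, b)


class TestTwas:
    def test_pipeline_shapes_and_determinism(self):
        sc = SimulationScenario(
            m=50, n=1000, n_ref=300,
            twas=TwasScenario(theta=0.2, pleiotropy_var=0.05, n_eqtl=465),
            seed=31,
        )
        st1, ss1, ref1 = simulate_twas(sc)
        st2, ss2, ref2 = simulate_twas(sc)
        assert ss1.m == 50 and len(st1.w_hat) == 50
        assert np.array_equal(ss1.z, ss2.z)
        assert np.array_equal(ref1.matrix, ref2.matrix)

    def test_theta_increases_signal(self):
        base = dict(m=50, n=2000, n_ref=300, seed=32)
        sc0 = SimulationScenario(twas=TwasScenario(theta=0.0,
                                                   pleiotropy_var=0.0), **base)
        sc1 = SimulationScenario(twas=TwasScenario(theta=0.5,
                                                   pleiotropy_var=0.0), **base)
        _, ss0, _ = simulate_twas(sc0)
        _, ss1, _ = simulate_twas(sc1)
        assert np.abs(ss1.z).max() > np.abs(ss0.z).max()


def test_reference_ld_converges_to_gwas_ld():
    big = simulate_genotypes(4000, 20, seed=33)
    target = empirical_ld(big).r
    dists = []
    for n_ref in (200, 800, 3200):
        ref = simulate_genotypes(n_ref, 20, seed=34)
        dists.append(np.linalg.norm(empirical_ld(ref).r - target))
    assert dists[2] < dists[0]
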