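"""Quadratic/linear Z-combination tests (BT, SKAT, SKAT-O, MLR, FLM, DOT)."""

import numpy as np
import pytest
from scipy import stats

from snpset.datatypes import SummaryStats
from snpset.ld import LdMatrix, empirical_ld
from snpset.quad import (BurdenTest, DotTest, FlmTest, MlrTest, SkatOTest,
                         SkatTest, burden_test, dot_test, flm_test, mlr_test,
                         skat_test, skato_test)
from snpset.simulate import marginal_gwas, simulate_genotypes

from conftest import ar_block_corr, mvn_draws


@pytest.fixture
def ld_half():
    return LdMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]))


class TestBurden:
    def test_single_snp_reduces_to_marginal(self):
        ss = SummaryStats.from_z([2.0])
        r = burden_test(ss, LdMatrix.identity(1))
        assert r.p == pytest.approx(2 * stats.norm.sf(2.0), rel=1e-12)

    def test_two_snp_arithmetic(self, ld_half):
        r = burden_test(SummaryStats.from_z([2.0, 2.0]), ld_half)
        assert r.stat == pytest.approx(4 / np.sqrt(3), rel=1e-9)
        assert r.p == pytest.approx(2 * stats.norm.sf(4 / np.sqrt(3)), rel=1e-9)

    def test_sign_cancellation(self):
        r = burden_test(SummaryStats.from_z([2.0, -2.0]), LdMatrix.identity(2))
        assert r.stat == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_degenerate_weights_error(self):
        ld = LdMatrix(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        with pytest.raises(ValueError, match="degenerate"):
            burden_test(SummaryStats.from_z([1.0, 1.0]), ld, w=[1.0, 1.0])


class TestSkat:
    def test_identity_reduces_to_chi2(self):
        r = skat_test(SummaryStats.from_z([2.0, 2.0]), LdMatrix.identity(2))
        assert r.stat == pytest.approx(8.0)
        assert r.p == pytest.approx(np.exp(-4.0), rel=1e-9)

    def test_single_snp_reduction(self):
        r = skat_test(SummaryStats.from_z([2.0]), LdMatrix.identity(1))
        assert r.p == pytest.approx(2 * stats.norm.sf(2.0), rel=1e-9)

    def test_correlated_matches_mvn_oracle(self):
        rho = 0.9
        rmat = np.array([[1.0, rho], [rho, 1.0]])
        r = skat_test(SummaryStats.from_z([2.0, 2.0]), LdMatrix(rmat))
        z = mvn_draws(rmat, 10**6, 3)
        mc = ((z**2).sum(axis=1) >= 8.0).mean()
        assert abs(r.p - mc) < 3 * np.sqrt(mc * (1 - mc) / 1e6)

    def test_random_small_instances_vs_monte_carlo(self):
        rng = np.random.default_rng(4)
        for trial in range(3):
            m = int(rng.integers(2, 6))
            a = rng.standard_normal((m + 3, m))
            rmat = np.corrcoef(a.T)
            z_obs = rng.standard_normal(m) * 1.5
            res = skat_test(SummaryStats.from_z(z_obs), LdMatrix(rmat))
            draws = mvn_draws(rmat, 10**6, 100 + trial)
            mc = ((draws**2).sum(axis=1) >= res.stat).mean()
            se = np.sqrt(mc * (1 - mc) / 1e6)
            assert abs(res.p - mc) < 3 * se + 1e-12

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            skat_test(SummaryStats.from_z([1.0, 1.0]), LdMatrix.identity(2),
                      w=[0.0, 0.0])


class TestSkatO:
    def test_grid_collapse_to_skat(self, ld_half):
        ss = SummaryStats.from_z([2.0, 2.0])
        assert skato_test(ss, ld_half, rho_grid=[0.0]).p == pytest.approx(
            skat_test(ss, ld_half).p, rel=1e-9
        )

    def test_grid_collapse_to_burden_squared(self, ld_half):
        ss1 = SummaryStats.from_z([1.0, 1.0])
        ss2 = SummaryStats.from_z([2.0, 2.0])
        p1 = skato_test(ss1, ld_half, rho_grid=[1.0]).p
        p2 = skato_test(ss2, ld_half, rho_grid=[1.0]).p
        assert p2 < p1  # monotone in |w'Z|

    def test_bonferroni_sandwich(self, ld_ar_small):
        rng = np.random.default_rng(5)
        grid = (0.0, 0.25, 0.5, 1.0)
        est = SkatOTest(rho_grid=grid).fit(ld_ar_small)
        comps = [SkatOTest(rho_grid=[r]).fit(ld_ar_small) for r in grid]
        for _ in range(10):
            z = rng.standard_normal(10)
            p_omni = est.transform(z[None, :])[0, 1]
            p_min = min(c.transform(z[None, :])[0, 1] for c in comps)
            assert p_omni >= p_min - 1e-3
            assert p_omni <= min(1.0, len(grid) * p_min) + 1e-3

    def test_null_calibration_full_grid(self):
        rmat = np.eye(8)
        z = mvn_draws(rmat, 10**4, 6)
        out = SkatOTest().fit(LdMatrix(rmat)).transform(z)
        rate = (out[:, 1] <= 0.05).mean()
        assert 0.04 <= rate <= 0.06


class TestMlr:
    def test_single_snp_large_n(self):
        r = mlr_test(SummaryStats.from_z([2.0]), LdMatrix.identity(1), n=10_000)
        assert r.p == pytest.approx(0.0455, abs=2e-4)

    def test_zero_z_gives_p_one(self, ld_ar_small):
        r = mlr_test(SummaryStats.from_z(np.zeros(10)), ld_ar_small, n=500)
        assert r.stat == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_matches_individual_level_regression(self):
        panel = simulate_genotypes(500, 10, seed=11)
        y = np.random.default_rng(12).standard_normal(500)
        ss = marginal_gwas(panel.matrix, y)
        r = mlr_test(ss, empirical_ld(panel), n=500)
        g = (panel.matrix - panel.matrix.mean(0)) / panel.matrix.std(0, ddof=1)
        x = np.column_stack([np.ones(500), g])
        bh, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss1 = ((y - x @ bh) ** 2).sum()
        rss0 = ((y - y.mean()) ** 2).sum()
        f = ((rss0 - rss1) / 10) / (rss1 / (500 - 11))
        p_ind = stats.f.sf(f, 10, 500 - 11)
        assert r.p == pytest.approx(p_ind, rel=0.02)

    def test_n_too_small(self, ld_ar_small):
        with pytest.raises(ValueError):
            mlr_test(SummaryStats.from_z(np.zeros(10)), ld_ar_small, n=11)


class TestFlm:
    def test_identity_basis_equals_mlr(self, ld_ar_small):
        ss = SummaryStats.from_z(np.linspace(-1, 2, 10))
        p_flm = flm_test(ss, ld_ar_small, n=500, positions=None, basis_k=25).p
        p_mlr = mlr_test(ss, ld_ar_small, n=500).p
        assert p_flm == pytest.approx(p_mlr, rel=1e-10)

    def test_zero_z(self):
        rmat = LdMatrix(0.95 * ar_block_corr(40, block=10) + 0.05 * np.eye(40))
        pos = np.arange(40) * 700
        r = flm_test(SummaryStats.from_z(np.zeros(40)), rmat, n=2000,
                     positions=pos)
        assert r.p == pytest.approx(1.0)

    def test_null_rate_not_anticonservative_with_exact_ld(self):
        rmat = 0.95 * ar_block_corr(40, block=10) + 0.05 * np.eye(40)
        z = mvn_draws(rmat, 10**4, 8)
        est = FlmTest(n=2000, positions=np.arange(40) * 700).fit(LdMatrix(rmat))
        rate = (est.transform(z)[:, 1] <= 0.05).mean()
        assert rate <= 0.06


class TestDot:
    def test_identity(self):
        r = dot_test(SummaryStats.from_z([2.0, 2.0]), LdMatrix.identity(2))
        assert r.stat == pytest.approx(8.0)
        assert r.p == pytest.approx(np.exp(-4.0), rel=1e-9)

    def test_zero_z(self, ld_ar_small):
        assert dot_test(SummaryStats.from_z(np.zeros(10)), ld_ar_small).p == 1.0

    def test_two_by_two_matches_linear_algebra(self):
        rmat = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = np.array([2.0, 2.0])
        s_expected = z @ np.linalg.inv(rmat) @ z
        r = dot_test(SummaryStats.from_z(z), LdMatrix(rmat))
        assert r.stat == pytest.approx(s_expected, rel=1e-12)


def test_permutation_invariance(ld_ar_small, rng):
    z = rng.standard_normal(10)
    ss = SummaryStats.from_z(z)
    perm = rng.permutation(10)
    ld_p = LdMatrix(ld_ar_small.r[np.ix_(perm, perm)])
    ss_p = SummaryStats.from_z(z[perm])
    for fn in (burden_test, skat_test, dot_test):
        assert fn(ss, ld_ar_small).p == pytest.approx(fn(ss_p, ld_p).p, rel=1e-8)
    p_a = skato_test(ss, ld_ar_small).p
    p_b = skato_test(ss_p, ld_p).p
    assert p_a == pytest.approx(p_b, rel=1e-6)
    p_m = mlr_test(ss, ld_ar_small, n=500).p
    p_mp = mlr_test(ss_p, ld_p, n=500).p
    assert p_m == pytest.approx(p_mp, rel=1e-8)
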