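"""Order-statistic tests: HC/GHC/BJ/GBJ, minP, GATES, SimpleM."""

import numpy as np
import pytest
from scipy import stats

from conftest import ar_block_corr, mvn_draws
from snpset.datatypes import SummaryStats, p_to_z, z_to_p
from snpset.ld import LdMatrix
from snpset.rank import (BjTest, GatesTest, GbjTest, GhcTest, HcTest,
                         MinPTest, SimpleMTest, bj_crossing_pvalue,
                         bj_stat_rows, hc_crossing_pvalue, hc_stat,
                         hc_stat_rows, minp_test, simplem_test,
                         uniform_noncrossing_prob)


class TestHcBjStatistics:
    def test_hc_hand_arithmetic(self):
        expected = np.sqrt(2) * 0.49 / np.sqrt(0.01 * 0.99)
        assert hc_stat([0.01, 0.5]) == pytest.approx(expected, rel=1e-6)

    def test_hc_no_exceedance(self):
        # all p near one: essentially no signal anywhere except the
        # vanishing top-rank slack, and the p-value is near one
        assert hc_stat([0.999] * 5) < 0.1
        est = HcTest().fit(np.eye(5))
        assert est.transform_pvalues(np.full((1, 5), 0.999))[0, 1] > 0.9

    def test_bj_hand_arithmetic(self):
        expected = 2 * (0.5 * np.log(50) + 0.5 * np.log(0.5 / 0.99))
        got = bj_stat_rows(np.array([[0.01, 0.5]]))[0]
        assert got == pytest.approx(expected, rel=1e-6)

    def test_bj_empty_max_is_zero(self):
        p = np.array([[0.9, 0.95, 1.0]])
        assert bj_stat_rows(p)[0] == pytest.approx(0.0, abs=1e-10)
        est = BjTest().fit(np.eye(3))
        assert est.transform_pvalues(p)[0, 1] == 1.0


class TestCrossingEngine:
    def test_noncrossing_single_uniform(self):
        # P(U > b) = 1 - b exactly
        assert uniform_noncrossing_prob(np.array([0.3])) == pytest.approx(0.7)

    def test_noncrossing_minimum_bound(self):
        # constant boundary b: P(all M uniforms > b) = (1-b)^M
        m, b = 6, 0.2
        got = uniform_noncrossing_prob(np.full(m, b))
        assert got == pytest.approx((1 - b) ** m, rel=1e-10)

    @pytest.mark.parametrize("est_cls, stat_fn, pfun", [
        (HcTest, hc_stat_rows, hc_crossing_pvalue),
        (BjTest, bj_stat_rows, bj_crossing_pvalue),
    ])
    def test_independence_calibration(self, est_cls, stat_fn, pfun):
        rng = np.random.default_rng(3)
        P = rng.uniform(size=(10_000, 20))
        out = est_cls().fit(np.eye(20)).transform_pvalues(P)
        rate = (out[:, 1] <= 0.05).mean()
        assert 0.03 <= rate <= 0.07


class TestGeneralized:
    def test_ghc_equals_hc_at_identity(self, rng):
        P = np.sort(rng.uniform(size=(50, 8)), axis=1)
        ghc = GhcTest().fit(np.eye(8))
        assert np.allclose(ghc._stat_rows(P), hc_stat_rows(P), rtol=1e-10)

    def test_gbj_equals_bj_at_identity(self, rng):
        P = np.sort(rng.uniform(size=(50, 8)), axis=1)
        gbj = GbjTest().fit(np.eye(8))
        assert np.allclose(gbj._stat_rows(P), bj_stat_rows(P), rtol=1e-10)

    def test_ghc_zero_z_central(self):
        r = 0.95 * ar_block_corr(6, block=3) + 0.05 * np.eye(6)
        est = GhcTest(n_draws=20_000).fit(LdMatrix(r))
        res = est.test(SummaryStats.from_z(np.zeros(6) + 1e-12))
        assert res.p >= 0.5

    def test_monte_carlo_path_flagged_and_calibrated(self):
        r = 0.95 * ar_block_corr(10, block=5) + 0.05 * np.eye(10)
        est = GbjTest(n_draws=50_000, seed=7).fit(LdMatrix(r))
        z = mvn_draws(r, 4000, 11)
        out = est.transform(z)
        assert est._last_detail["path"] == "mvn-monte-carlo"
        rate = (out[:, 1] <= 0.05).mean()
        # MC null drawn from the same LD: calibration should be tight
        assert 0.035 <= rate <= 0.065


class TestMinP:
    def test_independence_product(self):
        ss = SummaryStats.from_z(p_to_z(np.array([0.05, 0.9])))
        r = MinPTest().fit(np.eye(2)).test(ss)
        assert r.p == pytest.approx(1 - 0.95**2, abs=2e-4)

    def test_perfect_dependence_limit(self):
        r = np.array([[1.0, 0.9999], [0.9999, 1.0]])
        ss = SummaryStats.from_z(p_to_z(np.array([0.05, 0.0500001])))
        res = MinPTest().fit(LdMatrix(r)).test(ss)
        assert res.p == pytest.approx(0.05, abs=5e-3)

    def test_ar1_matches_mvn_oracle(self):
        r = 0.5 ** np.abs(np.subtract.outer(np.arange(3), np.arange(3))).astype(float)
        ss = SummaryStats.from_z(p_to_z(np.array([0.01, 0.9, 0.9])))
        p_an = MinPTest().fit(LdMatrix(r)).test(ss).p
        z = mvn_draws(r, 10**6, 9)
        mc = (z_to_p(z).min(axis=1) <= 0.01).mean()
        assert abs(p_an - mc) < 3 * np.sqrt(mc * (1 - mc) / 1e6) + 2e-4

    def test_monotone_in_min_p_and_correlation(self):
        r_lo = LdMatrix(np.array([[1.0, 0.2], [0.2, 1.0]]))
        r_hi = LdMatrix(np.array([[1.0, 0.9], [0.9, 1.0]]))
        p_small = MinPTest().fit(r_lo).transform_pvalues(
            np.array([[0.01, 0.5]]))[0, 1]
        p_large = MinPTest().fit(r_lo).transform_pvalues(
            np.array([[0.05, 0.5]]))[0, 1]
        assert p_small <= p_large
        p_hi = MinPTest().fit(r_hi).transform_pvalues(
            np.array([[0.01, 0.5]]))[0, 1]
        assert p_hi <= p_small + 1e-4


class TestGates:
    def test_identity_equals_simes(self):
        est = GatesTest().fit(np.eye(3))
        got = est.transform_pvalues(np.array([[0.01, 0.04, 0.9]]))[0, 1]
        assert got == pytest.approx(0.03, rel=1e-9)

    def test_perfect_correlation_collapses(self):
        r = np.array([[1.0, 0.9999], [0.9999, 1.0]])
        est = GatesTest().fit(LdMatrix(r))
        assert est.me_full_ == pytest.approx(1.0, abs=0.05)
        got = est.transform_pvalues(np.array([[0.05, 0.9]]))[0, 1]
        assert got == pytest.approx(0.05, rel=0.05)


class TestSimpleM:
    def test_identity_is_bonferroni(self):
        est = SimpleMTest().fit(np.eye(5))
        assert est.m_eff_ == 5
        got = est.transform_pvalues(np.array([[0.01, 0.5, 0.5, 0.5, 0.5]]))
        assert got[0, 1] == pytest.approx(0.05)

    def test_rank_one_spectrum(self):
        r = np.array([[1.0, 0.99], [0.99, 1.0]])
        est = SimpleMTest().fit(LdMatrix(r))
        assert est.m_eff_ == 1
        got = est.transform_pvalues(np.array([[0.03, 0.5]]))[0, 1]
        assert got == pytest.approx(0.03)


def test_permutation_invariance(rng):
    r = 0.95 * ar_block_corr(8, block=4) + 0.05 * np.eye(8)
    z = rng.standard_normal(8)
    perm = rng.permutation(8)
    rp = r[np.ix_(perm, perm)]
    for cls in (HcTest, BjTest, GhcTest, GbjTest, SimpleMTest, GatesTest):
        a = cls().fit(LdMatrix(r))._transform_z(z[None, :])[0][0]
        b = cls().fit(LdMatrix(rp))._transform_z(z[perm][None, :])[0][0]
        assert a == pytest.approx(b, rel=1e-9), cls.__name__


def test_strong_ld_inflation_of_independence_null_scans():
    """HC/BJ keep their independence-null p-values, which inflate under
    strong LD (the benchmark's central negative finding for these tests)."""
    r = 0.95 * ar_block_corr(20, rho=0.9, block=10) + 0.05 * np.eye(20)
    z = mvn_draws(r, 10_000, 13)
    for cls in (HcTest, BjTest):
        out = cls().fit(LdMatrix(r)).transform(z)
        ratio = (out[:, 1] <= 0.05).mean() / 0.05
        assert ratio > 1.2, cls.__name__
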