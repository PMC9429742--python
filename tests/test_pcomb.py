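"""LD-free p-value combiners: examples, reductions, oracles, calibration."""

import numpy as np
import pytest
from scipy import stats

from conftest import ar_block_corr, mvn_draws
from snpset.base import PCombTest
from snpset.datatypes import z_to_p
from snpset.pcomb import (AcatTest, ArtATest, ArtTest, FisherTest, GmTest,
                          HmpTest, RtpTest, SimesTest, TpmTest, acat_test,
                          art_test, arta_test, fisher_test, gm_test, hmp_test,
                          rtp_test, simes_test, tpm_test)

ALL_COMBINERS = (SimesTest, FisherTest, TpmTest, RtpTest, ArtTest, ArtATest,
                 GmTest, HmpTest, AcatTest)


class TestExamples:
    def test_simes(self):
        assert simes_test([0.5]).p == 0.5
        assert simes_test([0.01, 0.04, 0.9]).p == pytest.approx(0.03)
        assert simes_test([0.2, 0.2, 0.2]).p == pytest.approx(0.2)

    def test_fisher(self):
        assert fisher_test([1.0, 1.0]).p == pytest.approx(1.0)
        assert fisher_test([0.1]).p == pytest.approx(0.1, rel=1e-10)
        x = -2 * (np.log(0.01) + np.log(0.02))
        expected = np.exp(-x / 2) * (1 + x / 2)  # chi2_4 survival
        assert fisher_test([0.01, 0.02]).p == pytest.approx(expected, rel=1e-9)

    def test_tpm_no_truncated_terms(self):
        r = tpm_test([0.5, 0.9], tau=0.2)
        assert r.p == 1.0

    def test_tpm_tau_one_is_fisher(self):
        p = [0.01, 0.2, 0.7]
        assert tpm_test(p, tau=1.0).p == pytest.approx(fisher_test(p).p, rel=1e-9)

    def test_rtp_reductions(self):
        p = [0.01, 0.02, 0.5, 0.9]
        assert rtp_test(p, k=4).p == pytest.approx(fisher_test(p).p, rel=1e-9)
        assert rtp_test(p, k=1).p == pytest.approx(1 - 0.99**4, abs=1e-6)

    def test_art_k1_is_min_statistic(self):
        p = [0.01, 0.02, 0.5]
        assert art_test(p, k=1).p == pytest.approx(1 - 0.99**3, abs=1e-6)

    def test_gm_shape_one_is_fisher(self):
        p = [0.03, 0.4, 0.8]
        assert gm_test(p, a=1.0).p == pytest.approx(fisher_test(p).p, rel=1e-9)
        assert gm_test([0.2], a=0.0383).p == pytest.approx(0.2, rel=1e-8)

    def test_acat(self):
        assert acat_test([0.5, 0.5]).p == pytest.approx(0.5)
        assert acat_test([0.123]).p == pytest.approx(0.123, rel=1e-10)
        r = acat_test([0.01, 0.5])
        assert r.stat == pytest.approx(np.tan(0.49 * np.pi) / 2, rel=1e-9)
        assert r.p == pytest.approx(0.0200, abs=5e-4)

    def test_hmp_statistic_and_single(self):
        r = hmp_test([0.01, 0.5])
        assert r.stat == pytest.approx(1 / 51, rel=1e-12)
        assert abs(hmp_test([0.01]).p - 0.01) < 1e-3
        assert hmp_test([0.3, 0.3, 0.3]).stat == pytest.approx(0.3)


class TestOracles:
    def test_tpm_monte_carlo(self):
        rng = np.random.default_rng(7)
        u = rng.uniform(size=(10**6, 3))
        w = np.where(u <= 0.2, u, 1.0).prod(axis=1)
        mc = (w <= 0.01 * 0.1).mean()
        an = tpm_test([0.01, 0.1, 0.5], tau=0.2).p
        assert abs(an - mc) < 3 * np.sqrt(mc * (1 - mc) / 1e6)

    def test_rtp_monte_carlo(self):
        rng = np.random.default_rng(8)
        s = np.sort(rng.uniform(size=(10**6, 4)), axis=1)
        t = -np.log(s[:, :2]).sum(axis=1)
        mc = (t >= -np.log(0.01 * 0.02)).mean()
        an = rtp_test([0.01, 0.02, 0.5, 0.9], k=2).p
        assert abs(an - mc) < 3 * np.sqrt(mc * (1 - mc) / 1e6)

    def test_gm_monte_carlo(self):
        rng = np.random.default_rng(9)
        u = rng.uniform(size=(10**6, 3))
        t = stats.gamma.isf(u, 0.0383).sum(axis=1)
        tobs = stats.gamma.isf([0.01, 0.2, 0.9], 0.0383).sum()
        mc = (t >= tobs).mean()
        an = gm_test([0.01, 0.2, 0.9], a=0.0383).p
        assert abs(an - mc) < 3 * np.sqrt(mc * (1 - mc) / 1e6)

    def test_art_null_distribution_is_gamma(self):
        rng = np.random.default_rng(10)
        P = rng.uniform(size=(10_000, 10))
        out = ArtTest(k=4).fit(None).transform_pvalues(P)
        # exact Gamma(k) null => p-values uniform
        ks = stats.kstest(out[:, 1], "uniform")
        assert ks.pvalue > 0.01

    def test_hmp_landau_tail_matches_simulation(self):
        # finite-L accuracy improves with L; at L=200 the Landau tail is
        # within Monte-Carlo resolution of the exact harmonic-mean null
        rng = np.random.default_rng(11)
        L = 200
        s = (1.0 / rng.uniform(size=(10**6, L))).mean(axis=1)
        for point in (30.0, 60.0):
            mc = (s >= point).mean()
            # equal p-values 1/point give harmonic sum exactly `point`
            an = HmpTest().fit(None)._transform_p(
                np.full((1, L), 1.0 / point))[1][0]
            assert abs(an - mc) < 3 * np.sqrt(mc * (1 - mc) / 1e6) + 2e-4

    def test_arta_penalty_direction(self):
        p = [0.01, 0.2, 0.5, 0.9]
        grid = [1, 2]
        adaptive = arta_test(p, k_grid=grid, seed=5)
        best = min(art_test(p, k=k).p for k in grid)
        assert adaptive.p >= best


class TestCalibrationUnderIndependence:
    @pytest.mark.parametrize("cls", ALL_COMBINERS)
    def test_uniform_rate(self, cls):
        rng = np.random.default_rng(12)
        P = rng.uniform(size=(10_000, 12))
        out = cls().fit(None).transform_pvalues(P)
        rate = (out[:, 1] <= 0.05).mean()
        assert 0.03 <= rate <= 0.07, cls.__name__


@pytest.fixture(scope="module")
def strong_ld_pvalues():
    r = 0.95 * ar_block_corr(20, rho=0.9, block=10) + 0.05 * np.eye(20)
    return z_to_p(mvn_draws(r, 10_000, 14))


class TestDependenceBehaviour:
    """Mirrors the benchmark's headline split: harmonic-mean and Cauchy
    combiners tolerate LD, the multiplicative combiners inflate."""

    @pytest.mark.parametrize("cls", (HmpTest, AcatTest))
    def test_robust_combiners_stay_controlled(self, cls, strong_ld_pvalues):
        out = cls().fit(None).transform_pvalues(strong_ld_pvalues)
        ratio = (out[:, 1] <= 0.05).mean() / 0.05
        assert 0.8 <= ratio <= 1.2, cls.__name__

    @pytest.mark.parametrize("cls", (FisherTest, TpmTest, RtpTest, ArtTest,
                                     GmTest))
    def test_multiplicative_combiners_inflate(self, cls, strong_ld_pvalues):
        out = cls().fit(None).transform_pvalues(strong_ld_pvalues)
        ratio = (out[:, 1] <= 0.05).mean() / 0.05
        assert ratio > 1.2, cls.__name__


def test_monotone_in_each_input(rng):
    base = np.array([0.02, 0.3, 0.6])
    for cls in ALL_COMBINERS:
        est = cls().fit(None)
        p0 = est.transform_pvalues(base[None, :])[0, 1]
        worse = base.copy()
        worse[0] = 0.2
        p1 = est.transform_pvalues(worse[None, :])[0, 1]
        assert p1 >= p0 - 1e-9, cls.__name__


def test_permutation_invariance(rng):
    p = rng.uniform(size=5)
    for cls in ALL_COMBINERS:
        est = cls().fit(None)
        a = est.transform_pvalues(p[None, :])[0, 1]
        b = est.transform_pvalues(p[rng.permutation(5)][None, :])[0, 1]
        assert a == pytest.approx(b, rel=1e-9), cls.__name__
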