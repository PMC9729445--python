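"""Genomic cline function, likelihood, MCMC and outlier classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hybridzone import genomic_cline as gcl
from hybridzone.genotype_io import MISSING, GenotypeMatrix


def _gm(values, chrom=None):
    values = np.asarray(values, dtype=np.int8)
    n_ind, n_loci = values.shape
    meta = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * n_loci,
            "pos": np.arange(1, n_loci + 1) * 100,
            "rad_locus": [f"L{j}" for j in range(n_loci)],
        }
    )
    return GenotypeMatrix(values, [f"i{k}" for k in range(n_ind)], meta)


class TestPhi:
    def test_neutral_midpoint(self):
        assert gcl.phi(0.5, 0.0, 0.0) == 0.5

    def test_endpoints_anchored_for_extreme_parameters(self):
        assert gcl.phi(0.0, 5.0, -3.0) == 0.0
        assert gcl.phi(1.0, 5.0, -3.0) == 1.0

    def test_direct_substitution(self):
        assert gcl.phi(0.5, 0.4, 0.0) == pytest.approx(0.7)

    def test_out_of_range_h_errors(self):
        with pytest.raises(ValueError):
            gcl.phi(1.2, 0.0, 0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        h=st.floats(0, 1),
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
    )
    def test_bounded_and_anchored(self, h, a, b):
        v = gcl.phi(h, a, b)
        assert 0.0 <= v <= 1.0
        assert gcl.phi(0.0, a, b) == 0.0
        assert gcl.phi(1.0, a, b) == 1.0


class TestLocusLogLikelihood:
    def test_heterozygote_arithmetic(self):
        # pi = 0.5 -> logL = log(2 * 0.5 * 0.5) = log 0.5
        ll = gcl.locus_log_likelihood([1], [0.5], 0.0, 0.0, 0.25, 0.75)
        assert ll == pytest.approx(np.log(0.5))

    def test_all_missing_contributes_zero(self):
        ll = gcl.locus_log_likelihood([MISSING, MISSING], [0.2, 0.8], 0.5, -0.3, 0.1, 0.9)
        assert ll == 0.0

    def test_matches_enumeration_oracle(self):
        """10-individual fixture vs per-individual binomial-pmf sum."""
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 10)
        h = rng.uniform(0, 1, 10)
        for alpha, beta in [(0.0, 0.0), (0.8, -0.5), (-1.2, 1.0)]:
            ll = gcl.locus_log_likelihood(g, h, alpha, beta, 0.2, 0.85)
            oracle = 0.0
            for gi, hi in zip(g, h):
                ph = float(np.clip(hi + 2 * hi * (1 - hi) * (alpha + beta * (2 * hi - 1)), 0, 1))
                pi = ph * 0.85 + (1 - ph) * 0.2
                oracle += np.log(stats.binom.pmf(gi, 2, pi))
            assert ll == pytest.approx(oracle, abs=1e-12)

    def test_boundary_frequencies_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            gcl.locus_log_likelihood([1], [0.5], 0.0, 0.0, 0.0, 1.0)


def _simulate_loci(rng, h, alpha, beta, p0, p1):
    """Draw genotypes under the cline model for given per-locus parameters."""
    n, L = h.size, alpha.size
    ph = gcl.phi(h[:, None], alpha[None, :], beta[None, :])
    k1 = rng.binomial(2, ph)
    return (rng.binomial(k1, p1[None, :]) + rng.binomial(2 - k1, p0[None, :])).astype(np.int8)


@pytest.fixture(scope="module")
def null_fit():
    rng = np.random.default_rng(10)
    n, L = 150, 120
    h = rng.uniform(0.05, 0.95, n)
    alpha = np.zeros(L)
    beta = np.zeros(L)
    p0 = np.full(L, 0.03)
    p1 = np.full(L, 0.97)
    g = _simulate_loci(rng, h, alpha, beta, p0, p1)
    gm = _gm(g)
    return gcl.fit_genomic_clines_mcmc(
        gm, h, p0, p1, iterations=2000, burnin=1000, thin=5, seed=42
    )


class TestMCMC:

    def test_null_loci_intervals_cover_zero(self, null_fit):
        s = null_fit.summary
        cover_a = ((s["alpha_lo"] <= 0) & (s["alpha_hi"] >= 0)).mean()
        cover_b = ((s["beta_lo"] <= 0) & (s["beta_hi"] >= 0)).mean()
        assert cover_a >= 0.9 and cover_b >= 0.9

    def test_null_medians_centred(self, null_fit):
        # beta's leverage on Phi is bounded by ~0.1*beta (max of
        # 2h(1-h)(2h-1)), so its posterior is intrinsically ~2.5x wider
        # than alpha's at this sample size; the bounds reflect that
        s = null_fit.summary
        assert np.abs(s["alpha_med"]).mean() < 0.1
        assert np.abs(s["beta_med"]).mean() < 0.2

    def test_acceptance_rates_in_band(self, null_fit):
        r = null_fit.summary["accept_rate"]
        assert ((r > 0.1) & (r < 0.6)).all()

    def test_planted_beta_detected(self):
        rng = np.random.default_rng(11)
        n, L = 150, 150
        h = rng.uniform(0.05, 0.95, n)
        alpha = np.zeros(L)
        beta = np.zeros(L)
        beta[:10] = 1.0
        p0 = np.full(L, 0.03)
        p1 = np.full(L, 0.97)
        gm = _gm(_simulate_loci(rng, h, alpha, beta, p0, p1))
        fit = gcl.fit_genomic_clines_mcmc(
            gm, h, p0, p1, iterations=2500, burnin=1200, thin=5, seed=1
        )
        s = fit.summary
        planted = s.iloc[:10]
        assert (planted["beta_med"] > 0).all()
        # 80% power target at this sample size
        assert ((planted["beta_lo"] > 0).mean()) >= 0.8

    def test_same_seed_identical(self):
        rng = np.random.default_rng(12)
        h = rng.uniform(0.1, 0.9, 40)
        p0, p1 = np.full(30, 0.05), np.full(30, 0.95)
        gm = _gm(_simulate_loci(rng, h, np.zeros(30), np.zeros(30), p0, p1))
        f1 = gcl.fit_genomic_clines_mcmc(gm, h, p0, p1, iterations=500, burnin=200, seed=9)
        f2 = gcl.fit_genomic_clines_mcmc(gm, h, p0, p1, iterations=500, burnin=200, seed=9)
        pd.testing.assert_frame_equal(f1.summary, f2.summary)

    def test_no_admixed_errors(self):
        gm = _gm(np.zeros((4, 10)))
        with pytest.raises(ValueError, match="admixed"):
            gcl.fit_genomic_clines_mcmc(
                gm, np.zeros(4), np.full(10, 0.1), np.full(10, 0.9)
            )

    def test_posterior_draws_respect_anchoring(self, null_fit):
        """Phi at h=0 and h=1 is exactly 0/1 for every stored draw."""
        a = null_fit.alpha_samples[::50]
        b = null_fit.beta_samples[::50]
        assert np.all(gcl.phi(0.0, a, b) == 0.0)
        assert np.all(gcl.phi(1.0, a, b) == 1.0)

    def test_smaller_prior_shrinks_medians(self):
        rng = np.random.default_rng(13)
        h = rng.uniform(0.1, 0.9, 60)
        L = 40
        p0, p1 = np.full(L, 0.05), np.full(L, 0.95)
        beta = np.full(L, 0.8)
        gm = _gm(_simulate_loci(rng, h, np.zeros(L), beta, p0, p1))
        fits = {
            sd: gcl.fit_genomic_clines_mcmc(
                gm, h, p0, p1, iterations=1500, burnin=800, prior_sd=sd, seed=2
            )
            for sd in (1.0, 0.1)
        }
        m_wide = np.abs(fits[1.0].summary["beta_med"]).mean()
        m_narrow = np.abs(fits[0.1].summary["beta_med"]).mean()
        assert m_narrow < m_wide


class TestConvergenceCheck:
    def test_identical_chains_pass(self, ):
        rng = np.random.default_rng(14)
        h = rng.uniform(0.1, 0.9, 30)
        p0, p1 = np.full(20, 0.05), np.full(20, 0.95)
        gm = _gm(_simulate_loci(rng, h, np.zeros(20), np.zeros(20), p0, p1))
        f = gcl.fit_genomic_clines_mcmc(gm, h, p0, p1, iterations=600, burnin=300, seed=3)
        rep = gcl.check_convergence(f, f)
        assert rep["pass"].all()
        assert (rep["delta_alpha_med"] == 0).all()

    def test_independent_chains_mostly_agree(self):
        rng = np.random.default_rng(15)
        h = rng.uniform(0.05, 0.95, 120)
        L = 60
        p0, p1 = np.full(L, 0.03), np.full(L, 0.97)
        gm = _gm(_simulate_loci(rng, h, np.zeros(L), np.zeros(L), p0, p1))
        f1 = gcl.fit_genomic_clines_mcmc(gm, h, p0, p1, iterations=2000, burnin=1000, seed=4)
        f2 = gcl.fit_genomic_clines_mcmc(gm, h, p0, p1, iterations=1000, burnin=500, seed=5)
        rep = gcl.check_convergence(f1, f2, tol_median=0.1)
        assert rep["pass"].mean() >= 0.95

    def test_truncated_chain_flagged(self):
        rng = np.random.default_rng(16)
        h = rng.uniform(0.1, 0.9, 30)
        p0, p1 = np.full(10, 0.05), np.full(10, 0.95)
        gm = _gm(_simulate_loci(rng, h, np.zeros(10), np.zeros(10), p0, p1))
        f1 = gcl.fit_genomic_clines_mcmc(gm, h, p0, p1, iterations=600, burnin=300, seed=6)
        f2 = gcl.fit_genomic_clines_mcmc(gm, h, p0, p1, iterations=40, burnin=20, thin=5, seed=7)
        rep = gcl.check_convergence(f1, f2)
        assert rep["unreliable"].all()
        assert not rep["pass"].any()


def _fit_from_summary(summary: pd.DataFrame) -> gcl.GenomicClineFit:
    return gcl.GenomicClineFit(summary, np.empty((0, len(summary))), np.empty((0, len(summary))), 0, 0, 1, None)


class TestClassifyOutliers:
    def _null_summary(self, L=1000):
        rng = np.random.default_rng(17)
        med = rng.normal(0, 0.01, L)
        return pd.DataFrame(
            {
                "locus": np.arange(L),
                "chrom": "1",
                "pos": np.arange(L),
                "alpha_med": med,
                "alpha_lo": med - 0.5,
                "alpha_hi": med + 0.5,
                "beta_med": med,
                "beta_lo": med - 0.5,
                "beta_hi": med + 0.5,
                "accept_rate": 0.3,
            }
        )

    def test_concentrated_posteriors_give_no_outliers(self):
        out = gcl.classify_outliers(_fit_from_summary(self._null_summary()))
        assert not out["outlier"].any()

    def test_single_planted_extreme_beta(self):
        s = self._null_summary()
        s.loc[123, ["beta_med", "beta_lo", "beta_hi"]] = [2.0, 1.5, 2.5]
        out = gcl.classify_outliers(_fit_from_summary(s))
        assert out["pos_beta"].sum() == 1
        assert out.loc[123, "pos_beta"]
        # hand rule: CI excludes 0 and median in top 1% of medians
        assert s.loc[123, "beta_lo"] > 0
        assert s.loc[123, "beta_med"] >= np.quantile(s["beta_med"], 0.99)

    def test_tail_rule_caps_fraction(self):
        rng = np.random.default_rng(18)
        L = 1000
        med = rng.normal(0, 1.0, L)
        s = self._null_summary()
        s["beta_med"] = med
        s["beta_lo"] = med - 0.01
        s["beta_hi"] = med + 0.01  # every CI excludes 0
        out = gcl.classify_outliers(_fit_from_summary(s), tail=0.01)
        assert out["pos_beta"].mean() <= 0.01 + 1.0 / L

    def test_tail_validation(self):
        with pytest.raises(ValueError):
            gcl.classify_outliers(_fit_from_summary(self._null_summary()), tail=0.7)

    def test_category_labels(self):
        s = self._null_summary()
        s.loc[1, ["beta_med", "beta_lo", "beta_hi"]] = [2.0, 1.5, 2.5]
        s.loc[2, ["alpha_med", "alpha_lo", "alpha_hi"]] = [2.0, 1.5, 2.5]
        s.loc[2, ["beta_med", "beta_lo", "beta_hi"]] = [2.1, 1.6, 2.6]
        out = gcl.classify_outliers(_fit_from_summary(s))
        labels = gcl.outlier_category_labels(out)
        assert labels[1] == "+b"
        assert labels[2] == "multi"
        assert labels[0] == "none"
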