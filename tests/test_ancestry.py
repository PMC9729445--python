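"""Ancestry estimators, PCA, diagnostic panels and classification."""

import numpy as np
import pandas as pd
import pytest

from hybridzone import ancestry, synthetic_data as synth
from hybridzone.genotype_io import MISSING, GenotypeMatrix


def _gm(values, chrom=None):
    values = np.asarray(values, dtype=np.int8)
    n_ind, n_loci = values.shape
    meta = pd.DataFrame(
        {
            "chrom": chrom or ["1"] * n_loci,
            "pos": np.arange(1, n_loci + 1) * 10,
            "rad_locus": [f"L{j}" for j in range(n_loci)],
        }
    )
    return GenotypeMatrix(values, [f"i{k}" for k in range(n_ind)], meta)


class TestParentalFrequencies:
    def test_smoothed_arithmetic(self):
        gm = _gm(np.full((10, 1), 2))
        f = ancestry.parental_allele_frequencies(
            gm, [f"i{k}" for k in range(5)], [f"i{k}" for k in range(5, 10)]
        )
        assert f.p1[0] == pytest.approx((10 + 0.5) / (10 + 1))
        assert f.raw1[0] == 1.0

    def test_zero_pseudocount_boundary(self):
        gm = _gm(np.zeros((6, 1)))
        f = ancestry.parental_allele_frequencies(
            gm, ["i0", "i1", "i2"], ["i3", "i4", "i5"], pseudocount=0.0
        )
        assert f.p0[0] == 0.0 and f.p1[0] == 0.0

    def test_matches_bruteforce_recount(self, small_dataset):
        gm = small_dataset.genotypes
        p0_ids = small_dataset.samples.panel_ids("ref0")[:6]
        p1_ids = small_dataset.samples.panel_ids("ref1")[:6]
        f = ancestry.parental_allele_frequencies(gm, p0_ids, p1_ids, pseudocount=0.5)
        idx = {ind: i for i, ind in enumerate(gm.individuals)}
        for j in [0, 7, 101]:
            for ids, smoothed in ((p0_ids, f.p0), (p1_ids, f.p1)):
                calls = [gm.values[idx[p], j] for p in ids]
                calls = [c for c in calls if c != MISSING]
                expect = (sum(calls) + 0.5) / (2 * len(calls) + 1.0)
                assert smoothed[j] == pytest.approx(expect)

    def test_panel_validation(self, small_dataset):
        gm = small_dataset.genotypes
        with pytest.raises(ValueError, match="non-empty"):
            ancestry.parental_allele_frequencies(gm, [], ["x"])
        with pytest.raises(ValueError, match="disjoint"):
            ancestry.parental_allele_frequencies(
                gm, [gm.individuals[0]], [gm.individuals[0]]
            )


class TestHybridIndexML:
    def test_forced_to_one(self):
        gm = _gm(np.full((3, 100), 2))
        panel = np.zeros(100)
        f = ancestry.ParentalFreqs(
            p0=np.full(100, 0.005), p1=np.full(100, 0.995),
            raw0=panel, raw1=panel + 1, n0=np.full(100, 10), n1=np.full(100, 10),
        )
        est = ancestry.hybrid_index_ml(gm, f)
        assert (est["q"] >= 0.99).all()

    def test_flat_likelihood_degenerate(self):
        gm = _gm([[0, 1], [2, 1]])
        f = ancestry.ParentalFreqs(
            p0=np.array([0.4, 0.6]), p1=np.array([0.4, 0.6]),
            raw0=np.array([0.4, 0.6]), raw1=np.array([0.4, 0.6]),
            n0=np.array([10, 10]), n1=np.array([10, 10]),
        )
        est = ancestry.hybrid_index_ml(gm, f)
        assert (est["q"] == 0.5).all()
        assert est["degenerate"].all()
        assert (est["lo"] == 0.0).all() and (est["hi"] == 1.0).all()

    def test_all_missing_flagged(self):
        gm = _gm(np.full((1, 4), MISSING))
        f = ancestry.ParentalFreqs(
            p0=np.full(4, 0.1), p1=np.full(4, 0.9),
            raw0=np.full(4, 0.1), raw1=np.full(4, 0.9),
            n0=np.full(4, 10), n1=np.full(4, 10),
        )
        est = ancestry.hybrid_index_ml(gm, f)
        assert est["degenerate"].all() and np.isnan(est["q"]).all()

    def test_matches_grid_search_oracle(self, small_dataset):
        """Optimiser agrees with a 1e-4 grid search within 1e-3."""
        ds = small_dataset
        gm = ds.genotypes.take_individuals(np.arange(0, 120, 6))
        f = ancestry.parental_allele_frequencies(
            gm_full := ds.genotypes, ds.samples.panel_ids("ref0"), ds.samples.panel_ids("ref1")
        )
        est = ancestry.hybrid_index_ml(gm, f)
        use = f.defined
        grid = np.arange(0.0, 1.0 + 1e-4, 1e-4)
        pi = grid[:, None] * f.p1[use] + (1 - grid[:, None]) * f.p0[use]
        logs = np.log(pi)
        logs1m = np.log1p(-pi)
        for i in range(gm.n_individuals):
            g = gm.values[i, use]
            obs = g != MISSING
            ll = logs[:, obs] @ g[obs].astype(float) + logs1m[:, obs] @ (2.0 - g[obs])
            q_oracle = grid[np.argmax(ll)]
            assert abs(est["q"].iloc[i] - q_oracle) < 1e-3

    def test_profile_ci_brackets_estimate(self, small_dataset):
        ds = small_dataset
        f = ancestry.parental_allele_frequencies(
            ds.genotypes, ds.samples.panel_ids("ref0"), ds.samples.panel_ids("ref1")
        )
        est = ancestry.hybrid_index_ml(ds.genotypes, f)
        ok = ~est["degenerate"]
        assert ((est.loc[ok, "lo"] <= est.loc[ok, "q"]) & (est.loc[ok, "q"] <= est.loc[ok, "hi"])).all()


class TestAdmixtureEM:
    def test_two_pure_clusters_recovered(self):
        rng = np.random.default_rng(0)
        L = 200
        p0 = rng.uniform(0.0, 0.05, L)
        p1 = rng.uniform(0.95, 1.0, L)
        g0 = rng.binomial(2, p0, (25, L))
        g1 = rng.binomial(2, p1, (25, L))
        gm = _gm(np.vstack([g0, g1]))
        anchors = ([f"i{k}" for k in range(3)], [f"i{k}" for k in range(25, 28)])
        est, comp = ancestry.admixture_em(gm, seed=1, anchors=anchors)
        q = est["q"].to_numpy()
        assert np.all(q[:25] <= 0.02)
        assert np.all(q[25:] >= 0.98)

    def test_duplicated_individual_symmetry(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, (10, 60))
        base[0] = base[1]  # two identical individuals
        gm = _gm(base)
        est, _ = ancestry.admixture_em(gm, seed=3, anchors=None)
        assert est["q"].iloc[0] == pytest.approx(est["q"].iloc[1], abs=1e-6)

    def test_truth_correlation_on_transect(self, small_dataset):
        ds = small_dataset
        anchors = (ds.samples.panel_ids("ref0"), ds.samples.panel_ids("ref1"))
        est, _ = ancestry.admixture_em(ds.genotypes, seed=4, anchors=anchors, n_starts=3)
        truth = ds.truth_individuals.set_index("individual").loc[est["individual"], "true_h"]
        r = np.corrcoef(est["q"], truth)[0, 1]
        assert r >= 0.98


class TestPCA:
    def test_identical_individuals_identical_scores(self):
        rng = np.random.default_rng(5)
        v = rng.integers(0, 3, (6, 40))
        v[2] = v[3]
        gm = _gm(v)
        s = ancestry.genotype_pca(gm)
        np.testing.assert_allclose(s[2], s[3], atol=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        """4x4 scores equal direct covariance eigendecomposition up to sign."""
        v = np.array([[0, 1, 2, 0], [2, 1, 0, 1], [1, 2, 1, 2], [0, 0, 2, 1]])
        gm = _gm(v)
        s = ancestry.genotype_pca(gm, n_components=2)
        X = v - v.mean(axis=0)
        cov = X @ X.T / (4 - 1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][:2]
        expected = vecs[:, order] * np.sqrt(vals[order])
        for k in range(2):
            assert np.allclose(s[:, k], expected[:, k], atol=1e-9) or np.allclose(
                s[:, k], -expected[:, k], atol=1e-9
            )

    def test_pc1_mirrors_ancestry(self, small_dataset):
        ds = small_dataset
        truth = ds.truth_individuals["true_h"].to_numpy()
        s = ancestry.genotype_pca(ds.genotypes, orient_with=truth)
        assert abs(np.corrcoef(s[:, 0], truth)[0, 1]) >= 0.9

    def test_zero_variance_errors(self):
        gm = _gm(np.ones((3, 5)))
        with pytest.raises(ValueError, match="variance"):
            ancestry.genotype_pca(gm)


class TestDiagnosticPanel:
    def test_fixed_locus_included_and_partial_excluded(self):
        v = np.zeros((10, 2), dtype=np.int8)
        v[:5, 0] = 2  # panel1 fixed for counted allele
        v[:5, 1] = 2
        v[5, 1] = 1  # panel0 not fixed at locus 1
        gm = _gm(v)
        panel1 = [f"i{k}" for k in range(5)]
        panel0 = [f"i{k}" for k in range(5, 10)]
        out = ancestry.diagnostic_panel(gm, panel0, panel1, min_n=5)
        assert list(out["locus"]) == [0]
        assert list(out["orientation"]) == [1]

    def test_recovers_planted_fixed_loci(self, small_dataset):
        ds = small_dataset
        panel0 = ds.samples.panel_ids("ref0")
        panel1 = ds.samples.panel_ids("ref1")
        out = ancestry.diagnostic_panel(ds.genotypes, panel0, panel1, min_n=5)
        truly_fixed = set()
        idx = {ind: i for i, ind in enumerate(ds.genotypes.individuals)}
        r0 = [idx[p] for p in panel0]
        r1 = [idx[p] for p in panel1]
        for j in range(ds.genotypes.n_loci):
            c0 = ds.genotypes.values[r0, j]
            c1 = ds.genotypes.values[r1, j]
            c0, c1 = c0[c0 != MISSING], c1[c1 != MISSING]
            if len(c0) >= 5 and len(c1) >= 5:
                f0, f1 = c0.sum() / (2 * len(c0)), c1.sum() / (2 * len(c1))
                if abs(f1 - f0) == 1.0:
                    truly_fixed.add(j)
        assert truly_fixed
        assert len(set(out["locus"]) & truly_fixed) >= 0.95 * len(truly_fixed)


class TestHeterozygosity:
    def test_f1_and_pure_individuals(self):
        v = np.array([[1] * 6, [0] * 6, [2] * 6], dtype=np.int8)
        gm = _gm(v)
        panel = pd.DataFrame({"locus": np.arange(6), "chrom": "1", "pos": 1, "orientation": 1})
        H = ancestry.interspecific_heterozygosity(gm, panel)
        assert H.iloc[0] == 1.0
        assert H.iloc[1] == 0.0 and H.iloc[2] == 0.0

    def test_f2_cohort_mean_near_half(self):
        """h=0.5, alpha=beta=0 cohort: E[H] = 2h(1-h) = 0.5 within 3 SE."""
        rng = np.random.default_rng(8)
        n, L = 400, 50
        anc = rng.binomial(1, 0.5, (n, L, 2))
        geno = anc.sum(axis=2).astype(np.int8)  # p1=1, p0=0 diagnostic loci
        gm = _gm(geno)
        panel = pd.DataFrame({"locus": np.arange(L), "chrom": "1", "pos": 1, "orientation": 1})
        H = ancestry.interspecific_heterozygosity(gm, panel)
        se = np.sqrt(0.25 / (n * L))
        assert abs(H.mean() - 0.5) < 3 * se


class TestClassification:
    @pytest.mark.parametrize(
        "q,expected",
        [
            (0.999, "pure1"),
            (0.001, "pure0"),
            (0.95, "hybrid"),
            (0.05, "hybrid"),
            (0.5, "hybrid"),
            (0.97, "backcross-like"),
            (0.03, "backcross-like"),
        ],
    )
    def test_threshold_rules(self, q, expected):
        est = pd.DataFrame({"individual": ["x"], "q": [q]})
        out = ancestry.classify_individuals(est)
        assert out["class"].item() == expected

    def test_threshold_validation(self):
        est = pd.DataFrame({"individual": ["x"], "q": [0.5]})
        with pytest.raises(ValueError):
            ancestry.classify_individuals(est, pure_threshold=0.4)
        with pytest.raises(ValueError):
            ancestry.classify_individuals(est, pure_threshold=0.9, hybrid_threshold=0.95)
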