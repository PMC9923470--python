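import numpy as np
import pandas as pd
import pytest

from invcline import popstruct
from invcline.genio import MISSING, GenotypeMatrix
from invcline.popstruct import (
    ClusterResult,
    call_ak_genotypes,
    call_karyotypes,
    cluster_genotypes,
    ld_r2,
    observed_heterozygosity,
    pca,
    summarize_region,
    wc_fst,
)


def _matrix(dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    sites = pd.DataFrame({"contig": "c1",
                          "pos": np.arange(1, dosages.shape[0] + 1),
                          "ref": "A", "alt": "T", "mean_depth": 5.0})
    return GenotypeMatrix(dosages, sites,
                          [f"s{i}" for i in range(dosages.shape[1])])


class TestPca:
    def test_three_class_geometry(self):
        """Homozygote classes at the PC1 extremes with heterozygotes at the
        midpoint (dosage linearity, within 5% of the segment midpoint)."""
        dos = np.column_stack([np.zeros((40, 30)), np.ones((40, 30)),
                               np.full((40, 30), 2)]).astype(np.int8)
        g = _matrix(dos)
        res = pca(g, 2)
        s = res.scores[:, 0]
        c0, c1, c2 = s[:30].mean(), s[30:60].mean(), s[60:].mean()
        lo, hi = sorted([c0, c2])
        assert lo < c1 < hi
        span = hi - lo
        assert abs(c1 - 0.5 * (lo + hi)) < 0.05 * span

    def test_duplicated_individual_identical_scores(self, small_bundle):
        g = small_bundle.genotypes
        idx = np.concatenate([np.arange(g.n_samples), [0]])
        g2 = g.take_samples(idx)
        g2.samples[-1] = "dup"
        res = pca(g2, 3)
        np.testing.assert_allclose(res.scores[-1], res.scores[0], atol=1e-8)

    def test_zero_variance_raises(self):
        g = _matrix(np.zeros((5, 6)))
        with pytest.raises(ValueError, match="zero-variance"):
            pca(g)

    def test_explained_variance_fractions(self, small_bundle):
        res = pca(small_bundle.genotypes, 5)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1.0 + 1e-9


class TestClusterSelection:
    def test_single_blob_selects_k1(self):
        """Unstructured data — PCA-score-like input (many comparable noise
        dimensions) from one Gaussian blob — keeps k = 1."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 60))
        assert cluster_genotypes(X, range(1, 6), seed=0).k == 1

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError, match="fewer observations"):
            cluster_genotypes(np.zeros((5, 2)), range(1, 9))

    def test_whole_lg_three_clusters(self, transect_bundle):
        """The pruned-LG PCA resolves the two homokaryotype groups and the
        heterokaryotypes: k = 3."""
        g = transect_bundle.genotypes
        res = pca(g, g.n_samples - 1)
        clus = cluster_genotypes(res.scores, range(1, 11), seed=0)
        assert clus.k == 3

    def test_ak_contig_six_clusters(self, transect_bundle):
        """The allozyme contig resolves all six genotypes of three divergent
        haplotypes (BIC penalty; see methods note on criterion choice)."""
        g = transect_bundle.genotypes
        gak = g.take_sites(g.sites["contig"].to_numpy() == "contig_ak")
        res = pca(gak, g.n_samples - 1)
        clus = cluster_genotypes(res.scores, range(1, 11), seed=0,
                                 criterion="bic")
        assert clus.k == 6


class TestKaryotypeCalls:
    def test_concordance_with_truth(self, transect_bundle, karyotype_truth):
        g = transect_bundle.genotypes
        res = pca(g, g.n_samples - 1)
        clus = cluster_genotypes(res.scores, range(1, 11), seed=0)
        call = call_karyotypes(g, clus, transect_bundle.samples)
        assert (call.karyotype.to_numpy() == karyotype_truth).mean() >= 0.99

    def test_all_homozygous_input_raises(self):
        dos = np.where(np.random.default_rng(0).random((30, 30)) < 0.5, 0, 2)
        g = _matrix(dos)
        clus = ClusterResult(np.repeat([0, 1, 2], 10), 3, {}, np.zeros((3, 1)))
        samples = pd.DataFrame({"id": g.samples, "size_mm": 7.0})
        with pytest.raises(ValueError, match="ambiguous"):
            call_karyotypes(g, clus, samples)

    def test_allozyme_karyotype_table_mapping(self, transect_bundle,
                                              karyotype_truth):
        """Cross-tabulation of the six allozyme genotypes against karyotype:
        120/120 only in D/D, x/120 heterozygotes only in L/D, the rest only
        in L/L (the 120 allele counts the D arrangements)."""
        b = transect_bundle
        g = b.genotypes
        res = pca(g, g.n_samples - 1)
        clus = cluster_genotypes(res.scores, range(1, 11), seed=0)
        call = call_karyotypes(g, clus, b.samples)
        gak = g.take_sites(g.sites["contig"].to_numpy() == "contig_ak")
        clus6 = cluster_genotypes(pca(gak, g.n_samples - 1).scores,
                                  range(1, 11), seed=0, criterion="bic")
        ak = call_ak_genotypes(gak, clus6, call.karyotype)
        expected_kt = {"80/80": "L/L", "80/100": "L/L", "100/100": "L/L",
                       "80/120": "L/D", "100/120": "L/D", "120/120": "D/D"}
        ct = pd.crosstab(ak, call.karyotype)
        for geno, kt in expected_kt.items():
            if geno in ct.index:
                row = ct.loc[geno]
                assert row[kt] == row.sum()
        assert (ak.to_numpy() == np.array(b.truth.ak_genotypes)).mean() >= 0.99

    def test_heterokaryotype_heterozygosity_dominates(self, transect_bundle,
                                                      karyotype_truth):
        g = transect_bundle.genotypes
        kt = karyotype_truth
        h = {k: observed_heterozygosity(g, kt == k) for k in
             ("L/L", "L/D", "D/D")}
        assert h["L/D"] > h["L/L"] and h["L/D"] > h["D/D"]
        assert h["L/D"] > 1.5 * max(h["L/L"], h["D/D"])

    def test_triangle_corner_heterozygosity_ordering(self, transect_bundle):
        """Six allozyme clusters: the three corner (homozygote) clusters have
        lower H_obs than the three mid-edge (heterozygote) clusters."""
        b = transect_bundle
        gak = b.genotypes.take_sites(
            b.genotypes.sites["contig"].to_numpy() == "contig_ak")
        ak = np.array(b.truth.ak_genotypes)
        homo = {"80/80", "100/100", "120/120"}
        h = {gt: observed_heterozygosity(gak, ak == gt)
             for gt in np.unique(ak)}
        corner = [v for k, v in h.items() if k in homo]
        mid = [v for k, v in h.items() if k not in homo]
        assert max(corner) < min(mid)


class TestHeterozygosity:
    @pytest.mark.parametrize("dosages,expected", [
        (np.ones((4, 5)), 1.0),
        (np.array([[0, 2, 0, 2, 0]] * 3), 0.0),
        (np.array([[0, 1, 1, 2, MISSING]]), 0.5),
    ])
    def test_hand_counts(self, dosages, expected):
        g = _matrix(np.asarray(dosages))
        assert observed_heterozygosity(g) == pytest.approx(expected)

    def test_all_missing_site_excluded(self):
        g = _matrix(np.array([[1, 1, 1], [MISSING] * 3]))
        assert observed_heterozygosity(g) == pytest.approx(1.0)

    def test_empty_group_raises(self):
        g = _matrix(np.ones((2, 3)))
        with pytest.raises(ValueError, match="empty"):
            observed_heterozygosity(g, np.array([], dtype=int))


def _wc_oracle(ga, gb):
    """Independently coded textbook variance-components theta-hat for one
    site and two groups of diploid genotypes (0/1/2 lists)."""
    import math
    ga, gb = list(ga), list(gb)
    n1, n2 = len(ga), len(gb)
    p1 = sum(ga) / (2 * n1)
    p2 = sum(gb) / (2 * n2)
    h1 = sum(1 for x in ga if x == 1) / n1
    h2 = sum(1 for x in gb if x == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    ssq = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (ssq - (pbar * (1 - pbar) - (r - 1) * ssq / r
                              - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) * ssq / r
                               - (2 * nbar - 1) * hbar / (4 * nbar))
    c = hbar / 2
    if a + b + c == 0:
        return math.nan
    return a / (a + b + c)


class TestWcFst:
    def test_null_sites_near_zero(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.5, size=(400, 100)).astype(np.int8)
        g = _matrix(dos)
        _, mean = wc_fst(g, np.arange(50), np.arange(50, 100))
        assert abs(mean) < 0.01

    def test_fixed_difference_is_one(self):
        g = _matrix(np.array([[0, 0, 0, 2, 2, 2]]))
        theta, mean = wc_fst(g, [0, 1, 2], [3, 4, 5])
        assert theta[0] == pytest.approx(1.0)

    def test_example_matches_oracle(self):
        ga, gb = [0, 0, 1], [2, 2, 1]
        g = _matrix(np.array([ga + gb]))
        theta, _ = wc_fst(g, [0, 1, 2], [3, 4, 5])
        assert theta[0] == pytest.approx(_wc_oracle(ga, gb), abs=1e-12)

    def test_exhaustive_small_tables_match_oracle(self):
        """Every two-group genotype table with up to 4 diploids per group
        agrees with the independent variance-components oracle."""
        from itertools import combinations_with_replacement
        tables = []
        for n in (1, 2, 3, 4):
            tables += [list(t) for t in
                       combinations_with_replacement((0, 1, 2), n)]
        rows, pairs = [], []
        for ga in tables:
            for gb in tables:
                if len(ga) < 2 or len(gb) < 2:
                    continue
                pairs.append((ga, gb))
                rows.append(ga + gb + [MISSING] * (8 - len(ga) - len(gb)))
        g = _matrix(np.array(rows, dtype=np.int8))
        n_a = [len(ga) for ga, _ in pairs]
        # groups must align per row; run row-by-row on sliced matrices
        for j, (ga, gb) in enumerate(pairs):
            gj = g.take_sites([j])
            theta, _ = wc_fst(gj, np.arange(len(ga)),
                              np.arange(len(ga), len(ga) + len(gb)))
            expected = _wc_oracle(ga, gb)
            if np.isnan(expected):
                assert np.isnan(theta[0])
            else:
                assert theta[0] == pytest.approx(expected, abs=1e-10)

    def test_overlapping_groups_raise(self):
        g = _matrix(np.zeros((2, 6)))
        with pytest.raises(ValueError, match="overlap"):
            wc_fst(g, [0, 1, 2], [2, 3, 4])


class TestLdR2:
    def test_site_against_itself(self):
        rng = np.random.default_rng(0)
        g = _matrix(rng.binomial(2, 0.5, size=(3, 50)).astype(np.int8))
        r2, idx = ld_r2(g, maf_min=0.1)
        np.testing.assert_allclose(np.diag(r2), 1.0, atol=1e-12)

    def test_independent_sites_low_r2(self):
        rng = np.random.default_rng(2)
        g = _matrix(rng.binomial(2, 0.5, size=(40, 500)).astype(np.int8))
        r2, idx = ld_r2(g, maf_min=0.1)
        off = r2[np.triu_indices(len(idx), k=1)]
        assert np.nanmean(off) < 0.01

    def test_matches_dosage_correlation_oracle(self):
        x = np.array([0, 0, 1, 2])
        y = np.array([0, 1, 1, 2])
        g = _matrix(np.stack([x, y]))
        r2, _ = ld_r2(g, maf_min=0.0)
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert r2[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_with_missing(self):
        x = np.array([0, 0, 1, 2, MISSING])
        y = np.array([0, 1, 1, 2, 2])
        g = _matrix(np.stack([x, y]))
        r2, _ = ld_r2(g, maf_min=0.0)
        expected = np.corrcoef(x[:4], y[:4])[0, 1] ** 2
        assert r2[0, 1] == pytest.approx(expected, abs=1e-12)


class TestSummarizeRegion:
    def test_uniform_values(self):
        fst = np.full(30, 0.5)
        cm = np.linspace(0, 69, 30)
        out = summarize_region(fst, cm, (11, 58))
        assert out["fst_inside"] == out["fst_outside"] == out["fst_whole"] == 0.5

    def test_whole_lg_interval_consistency(self):
        rng = np.random.default_rng(0)
        fst = rng.random(40)
        cm = np.linspace(0, 69, 40)
        out = summarize_region(fst, cm, (0, 69))
        assert out["fst_inside"] == pytest.approx(out["fst_whole"])
        assert out["n_sites_outside"] == 0
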