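"""Association engine: transform, PC correction, scan algebra, stratified
FDR, replication pi1."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from meqtlseq import scan as sc
from meqtlseq.datatypes import GenotypeMatrix
from meqtlseq.errors import CollinearityError, ConfigError, DegenerateSiteError


def make_geno(dosages, chroms, positions, is_cpg=None):
    n, S = dosages.shape
    snps = pd.DataFrame({
        "snp": [f"snp{j}" for j in range(S)], "chrom": chroms, "pos": positions,
        "ref": "A", "alt": "T",
        "maf": np.minimum(dosages.mean(0) / 2, 1 - dosages.mean(0) / 2),
        "is_cpg_snp": np.zeros(S, bool) if is_cpg is None else is_cpg})
    return GenotypeMatrix(dosages=dosages.astype(float), snps=snps,
                          subjects=[f"S{i}" for i in range(n)])


class TestInverseQuantileNormal:
    def test_three_distinct_values(self):
        out = sc.inverse_quantile_normal([5.0, 1.0, 3.0])
        expect = stats.norm.ppf([(r - 0.5) / 3 for r in (3, 1, 2)])
        assert np.allclose(out, expect)
        assert out[1] == pytest.approx(-0.9674, abs=1e-4)
        assert out[0] == pytest.approx(0.9674, abs=1e-4)
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=25)
        out = sc.inverse_quantile_normal(v)
        assert np.array_equal(np.argsort(out), np.argsort(v))

    def test_ties_share_average_rank(self):
        out = sc.inverse_quantile_normal([1.0, 2.0, 2.0, 5.0])
        assert out[1] == out[2]
        assert out[1] == pytest.approx(stats.norm.ppf((2.5 - 0.5) / 4))

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateSiteError):
            sc.inverse_quantile_normal([2.0, 2.0, 2.0])

    def test_matrix_transform_drops_constant(self):
        M = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        out, kept = sc.quantile_normalize_columns(M, on_constant="drop")
        assert out.shape == (10, 1) and kept.tolist() == [True, False]


class TestMethylationPCs:
    def test_scores_orthogonal_variance_sorted(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(30, 200))
        scores, var = sc.compute_methylation_pcs(M, k=7)
        c = scores.T @ scores
        off = c - np.diag(np.diag(c))
        assert np.abs(off).max() < 1e-8
        assert np.all(np.diff(var) <= 1e-9)

    def test_planted_confounder_recovered(self):
        rng = np.random.default_rng(2)
        mix = rng.random(50)
        load = rng.normal(size=300)
        M = np.outer(mix, load) * 3 + rng.normal(0, 0.5, size=(50, 300))
        scores, _ = sc.compute_methylation_pcs(M, k=3)
        assert abs(np.corrcoef(scores[:, 0], mix)[0, 1]) > 0.9

    def test_k_too_large(self):
        with pytest.raises(ConfigError):
            sc.compute_methylation_pcs(np.zeros((5, 10)), k=5)


class TestScanAlgebra:
    def test_matches_per_pair_ols(self):
        """Residualize-then-correlate equals OLS with genotype + covariates."""
        rng = np.random.default_rng(3)
        n, S, P = 20, 5, 5
        G = rng.integers(0, 3, size=(n, S)).astype(float)
        M = rng.normal(size=(n, P))
        X = rng.normal(size=(n, 3))
        t, p = sc.association_scan_matrix(G, M, X)
        for j in range(S):
            for k in range(P):
                design = sm.add_constant(np.column_stack([G[:, j], X]))
                fit = sm.OLS(M[:, k], design).fit()
                assert t[j, k] == pytest.approx(fit.tvalues[1], abs=1e-8)
                assert p[j, k] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_orthogonal_pair_is_null(self):
        g = np.array([[1, -1, 1, -1, 1, -1, 1, -1]], dtype=float).T
        m = np.array([[1, 1, -1, -1, 1, 1, -1, -1]], dtype=float).T
        t, p = sc.association_scan_matrix(g, m, None)
        assert t[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert p[0, 0] == pytest.approx(1.0)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(4)
        n = 50
        G = rng.integers(0, 3, size=(n, 100)).astype(float)
        M = rng.normal(size=(n, 100))
        X = rng.normal(size=(n, 2))
        _, p = sc.association_scan_matrix(G, M, X)
        rate = (p < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=12)})
        X["b"] = 2 * X["a"]
        with pytest.raises(CollinearityError, match="b"):
            sc.association_scan_matrix(rng.normal(size=(12, 2)),
                                       rng.normal(size=(12, 2)), X)


class TestStratum:
    def test_local_at_900kb(self):
        s, d = sc.classify_stratum("chr1", 1_500_000, "chr1", 2_400_000, 2_400_100)
        assert (s, d) == ("local", 900_000)

    def test_boundary_exactly_1mb_is_local(self):
        s, d = sc.classify_stratum("chr1", 0, "chr1", 1_000_000, 1_000_010)
        assert (s, d) == ("local", 1_000_000)
        s2, _ = sc.classify_stratum("chr1", 0, "chr1", 1_000_001, 1_000_010)
        assert s2 == "distant_same_chr"

    def test_cross_chromosome(self):
        s, d = sc.classify_stratum("chr1", 5, "chr2", 10, 20)
        assert s == "cross_chr" and np.isinf(d)

    def test_inside_site_distance_zero(self):
        s, d = sc.classify_stratum("chr1", 150, "chr1", 100, 200)
        assert (s, d) == ("local", 0)

    def test_count_tests_zero_snps(self):
        g = make_geno(np.zeros((3, 0)), [], [])
        sites = pd.DataFrame({"site": ["a"], "chrom": ["chr1"],
                              "start": [0], "end": [10]})
        c = sc.count_tests(g, sites)
        assert c == {"local": 0, "distant_same_chr": 0, "cross_chr": 0, "total": 0}

    def test_count_tests_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        n_snps, n_sites = 100, 100
        chroms = np.where(rng.random(n_snps) < 0.5, "chr1", "chr2")
        pos = rng.integers(0, 3_000_000, n_snps)
        g = make_geno(rng.integers(0, 3, (4, n_snps)), chroms, pos)
        g.snps.sort_values(["chrom", "pos"], inplace=True, ignore_index=True)
        st = rng.integers(0, 3_000_000, n_sites)
        sites = pd.DataFrame({
            "site": [f"m{i}" for i in range(n_sites)],
            "chrom": np.where(rng.random(n_sites) < 0.5, "chr1", "chr2"),
            "start": st, "end": st + rng.integers(50, 500, n_sites)})
        got = sc.count_tests(g, sites, window=1_000_000)
        oracle = {"local": 0, "distant_same_chr": 0, "cross_chr": 0}
        for _, srow in g.snps.iterrows():
            for _, mrow in sites.iterrows():
                s, _ = sc.classify_stratum(srow["chrom"], srow["pos"],
                                           mrow["chrom"], mrow["start"],
                                           mrow["end"])
                oracle[s] += 1
        oracle["total"] = n_snps * n_sites
        assert got == oracle


class TestFdr:
    def test_all_p_one_no_discoveries(self):
        res, flags = sc.stratified_bh_fdr(np.ones(10), ["local"] * 10)
        assert not flags.any()
        assert res[0].k == 0 and np.isnan(res[0].p_threshold)

    def test_worked_example(self):
        """m=4, alpha=0.01: thresholds (k/m)a = .0025,.005,.0075,.01 ->
        P(2)=0.002 <= 0.005 is the last pass, k*=2."""
        p = np.array([0.001, 0.002, 0.5, 0.9])
        res, flags = sc.stratified_bh_fdr(p, ["local"] * 4, alpha=0.01)
        assert res[0].k == 2
        assert res[0].p_threshold == pytest.approx(0.002)
        assert flags.tolist() == [True, True, False, False]

    def test_empty_stratum_reported_na(self):
        res, _ = sc.stratified_bh_fdr(np.array([0.5]), ["local"])
        by = {r.stratum: r for r in res}
        assert by["cross_chr"].k == 0 and np.isnan(by["cross_chr"].p_threshold)

    def test_truncated_input_with_m_override(self):
        """BH on a p<=cutoff subset with the true m gives the same threshold
        as BH on the full vector."""
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(size=5000), rng.uniform(0, 1e-5, 50)])
        full, _ = sc.stratified_bh_fdr(p, ["local"] * p.size, alpha=0.05)
        kept = p[p <= 1e-3]
        trunc, _ = sc.stratified_bh_fdr(kept, ["local"] * kept.size, alpha=0.05,
                                        m_per_stratum={"local": p.size})
        assert full[0].k == trunc[0].k
        assert full[0].p_threshold == pytest.approx(trunc[0].p_threshold)

    def test_fdr_controlled_in_simulation(self):
        """Mean realized FDP <= ~alpha over replicates of null + alternatives."""
        rng = np.random.default_rng(8)
        alpha, fdps = 0.05, []
        for _ in range(100):
            p = np.concatenate([rng.uniform(size=2000), rng.uniform(0, 1e-7, 100)])
            is_null = np.arange(p.size) < 2000
            _, flags = sc.stratified_bh_fdr(p, ["local"] * p.size, alpha=alpha)
            fdps.append((flags & is_null).sum() / max(1, flags.sum()))
        assert np.mean(fdps) <= alpha * 1.2

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigError):
            sc.stratified_bh_fdr(np.array([1.5]), ["local"])


class TestPi1:
    def test_all_tiny_p(self):
        r = sc.pi1_replication(np.full(5000, 1e-8))
        assert r.pi1 == 1.0

    def test_uniform_null(self):
        rng = np.random.default_rng(9)
        r = sc.pi1_replication(rng.uniform(size=10_000))
        assert r.pi1 == pytest.approx(0.0, abs=0.02)

    def test_mixture_recovered(self):
        rng = np.random.default_rng(10)
        p = np.concatenate([rng.uniform(size=7000), rng.uniform(0, 1e-6, 3000)])
        r = sc.pi1_replication(p)
        assert r.pi1 == pytest.approx(0.30, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            sc.pi1_replication(np.array([]))


class TestPcGenotypeCheck:
    def test_null_lambda_near_one(self):
        rng = np.random.default_rng(11)
        n, S = 150, 3000
        g = make_geno(rng.integers(0, 3, (n, S)).astype(float),
                      ["chr1"] * S, np.arange(S) * 1000)
        pcs = rng.normal(size=(n, 2))
        out = sc.pc_genotype_check(pcs, g)
        assert np.allclose(out["lambda_gc"], 1.0, atol=0.1)
        assert (out["min_p_bonferroni"] > 0.01).all()

    def test_pc_equal_to_dosage_detected(self):
        rng = np.random.default_rng(12)
        n = 100
        D = rng.integers(0, 3, (n, 50)).astype(float)
        g = make_geno(D, ["chr1"] * 50, np.arange(50) * 1000)
        pcs = D[:, [7]] + rng.normal(0, 1e-6, (n, 1))
        out = sc.pc_genotype_check(pcs, g)
        assert out["min_p_bonferroni"].iloc[0] < 1e-10


class TestSummarize:
    def _inputs(self):
        rng = np.random.default_rng(13)
        g = make_geno(rng.integers(0, 3, (10, 3)).astype(float),
                      ["chr1"] * 3, [100, 200, 300])
        sites = pd.DataFrame({"site": ["a", "b"], "chrom": ["chr1"] * 2,
                              "start": [150, 5000], "end": [160, 5100]})
        counts = {"local": 6, "distant_same_chr": 0, "cross_chr": 0, "total": 6}
        fdr = [sc.FdrResult("local", 6, 0.01, 2, 1e-4),
               sc.FdrResult("distant_same_chr", 0, 0.01, 0, float("nan")),
               sc.FdrResult("cross_chr", 0, 0.01, 0, float("nan"))]
        return g, sites, counts, fdr

    def test_no_significant_pairs(self):
        g, sites, counts, fdr = self._inputs()
        results = pd.DataFrame({"snp": [], "site": [], "stratum": [],
                                "p": [], "significant": []})
        out = sc.summarize_results(results, fdr, counts, sites, g)
        assert (out["unique_snps"] == 0).all()
        assert (out["unique_sites"] == 0).all()

    def test_unique_counting(self):
        g, sites, counts, fdr = self._inputs()
        results = pd.DataFrame({
            "snp": ["snp0", "snp0"], "site": ["a", "b"],
            "stratum": ["local", "local"], "p": [1e-6, 1e-6],
            "significant": [True, True]})
        out = sc.summarize_results(results, fdr, counts, sites, g)
        local = out[out["stratum"] == "local"].iloc[0]
        assert local["unique_snps"] == 1 and local["unique_sites"] == 2
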