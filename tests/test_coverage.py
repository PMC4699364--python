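"""Coverage measures: survival estimation, the expected-coverage sum,
site collapsing, background filter and region masks."""
import numpy as np
import pandas as pd
import pytest

from meqtlseq import coverage as cov
from meqtlseq.datatypes import CoverageMatrix, FragmentSizeModel, Reads
from meqtlseq.dists import FragmentLengthDistribution
from meqtlseq.errors import ConfigError, EstimationError


def make_reads(pos5, strand, subject=None, chrom_names=("chr1",),
               subjects=("S0",), read_len=50, chrom_code=None):
    pos5 = np.asarray(pos5, dtype=np.int64)
    n = pos5.size
    return Reads(
        chrom_code=np.zeros(n, np.int16) if chrom_code is None else np.asarray(chrom_code, np.int16),
        pos5=pos5,
        strand=np.asarray(strand, np.int8),
        subject=np.zeros(n, np.int32) if subject is None else np.asarray(subject, np.int32),
        chrom_names=list(chrom_names), subjects=list(subjects), read_len=read_len)


class TestIsolatedCpgs:
    def test_far_apart_both_returned(self):
        out = cov.find_isolated_cpgs(np.array([100, 10_000]), 400)
        assert out.tolist() == [100, 10_000]

    def test_close_pair_excluded(self):
        assert cov.find_isolated_cpgs(np.array([100, 300]), 400).size == 0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = np.sort(rng.choice(5000, size=60, replace=False))
            gap = int(rng.integers(10, 500))
            got = cov.find_isolated_cpgs(pos, gap)
            oracle = [p for p in pos
                      if not any(q != p and abs(q - p) <= gap for q in pos)]
            assert got.tolist() == oracle

    def test_unsorted_rejected(self):
        with pytest.raises(ConfigError):
            cov.find_isolated_cpgs(np.array([50, 10]), 100)


class TestFragmentSizeModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            FragmentSizeModel(survival=np.array([1.0, 0.5, 0.7] + [0.1] * 60),
                              read_len=2)  # not non-increasing
        with pytest.raises(ValueError):
            FragmentSizeModel(survival=np.concatenate([[1.0, 0.5], np.full(60, 0.4)]),
                              read_len=3)  # <1 inside read

    def test_prob_covers_zero_beyond_dmax(self):
        m = FragmentSizeModel(survival=np.ones(100), read_len=50)
        assert m.prob_covers(np.array([99, 100, 150])).tolist() == [1.0, 0.0, 0.0]


def _reads_around_isolated(lengths, n_frag, rng, spacing=5000, read_len=50):
    """Fragments covering isolated CpGs with 5' offset uniform in [0, L)."""
    n_cpg = 200
    cpgs = (np.arange(n_cpg) + 1) * spacing
    anchor = rng.choice(cpgs, size=n_frag)
    L = lengths(rng, n_frag)
    off = (rng.random(n_frag) * L).astype(np.int64)
    strand = np.where(rng.random(n_frag) < 0.5, 1, -1)
    pos5 = np.where(strand > 0, anchor - off, anchor + off)
    return make_reads(pos5, strand, read_len=read_len), {"chr1": cpgs}


class TestSurvivalEstimation:
    def test_fixed_length_step_recovered(self):
        rng = np.random.default_rng(1)
        reads, iso = _reads_around_isolated(
            lambda r, n: np.full(n, 125), 40_000, rng)
        m = cov.estimate_fragment_size_distribution(reads, iso, 50, 300)
        assert np.all(m.survival[:121] >= 0.95)
        assert np.all(m.survival[130:] <= 0.05)

    def test_gamma_median_recovered(self):
        """Length-biased placement + uniform offsets reproduce S(125)=0.5."""
        dist = FragmentLengthDistribution.gamma(median=125)
        rng = np.random.default_rng(2)
        reads, iso = _reads_around_isolated(
            lambda r, n: dist.sample_length_biased(r, n), 60_000, rng)
        m = cov.estimate_fragment_size_distribution(reads, iso, 50, 500)
        assert m.survival[125] == pytest.approx(0.5, abs=0.05)

    def test_no_reads_raises(self):
        reads = make_reads([], [])
        with pytest.raises(EstimationError):
            cov.estimate_fragment_size_distribution(reads, {"chr1": np.array([100])})


class TestMethylationMeasure:
    def model(self):
        s = np.ones(301)
        s[50:] = np.linspace(1, 0, 251)
        s[200] = 0.4
        s = np.minimum.accumulate(s)
        return FragmentSizeModel(survival=s, read_len=50)

    def test_sequenced_part_full_unit(self):
        reads = make_reads([100], [1])
        m = cov.compute_methylation_measure(reads, {"chr1": np.array([120])},
                                            self.model())
        assert m.values[0, 0] == 1.0

    def test_probabilistic_tail_uses_survival(self):
        model = self.model()
        reads = make_reads([100], [1])
        m = cov.compute_methylation_measure(reads, {"chr1": np.array([300])}, model)
        assert m.values[0, 0] == pytest.approx(model.survival[200])

    def test_minus_strand_mirrored(self):
        model = self.model()
        m = cov.compute_methylation_measure(
            make_reads([500], [-1]), {"chr1": np.array([480, 300])}, model)
        assert m.values[0, np.argmax(m.positions == 480)] == 1.0
        assert m.values[0, np.argmax(m.positions == 300)] == pytest.approx(
            model.survival[200])

    def test_linearity_in_reads(self):
        rng = np.random.default_rng(3)
        model = self.model()
        cpgs = {"chr1": np.sort(rng.choice(10_000, 50, replace=False))}
        p1 = rng.integers(0, 10_000, 200)
        p2 = rng.integers(0, 10_000, 300)
        s1 = np.where(rng.random(200) < 0.5, 1, -1)
        s2 = np.where(rng.random(300) < 0.5, 1, -1)
        a = cov.compute_methylation_measure(make_reads(p1, s1), cpgs, model)
        b = cov.compute_methylation_measure(make_reads(p2, s2), cpgs, model)
        both = cov.compute_methylation_measure(
            make_reads(np.concatenate([p1, p2]), np.concatenate([s1, s2])),
            cpgs, model)
        assert np.allclose(both.values, a.values + b.values)

    def test_monte_carlo_matches_true_coverage(self):
        """Expected-coverage measure is an unbiased predictor of realized
        fragment coverage when starts are uniform and lengths independent."""
        dist = FragmentLengthDistribution.gamma(median=125)
        rng = np.random.default_rng(4)
        cpgs = (np.arange(300) + 1) * 2000
        n_frag = 60_000
        anchor = rng.choice(cpgs, size=n_frag)
        start = anchor - rng.integers(0, 600, n_frag)  # uniform, coverage not guaranteed
        L = dist.sample(rng, n_frag)
        reads = make_reads(start, np.ones(n_frag), read_len=50)
        model = FragmentSizeModel(survival=dist.survival(500), read_len=50)
        meas = cov.compute_methylation_measure(reads, {"chr1": cpgs}, model)
        true_cov = np.zeros(cpgs.size)
        idx = np.searchsorted(cpgs, start)
        covered = (cpgs[np.minimum(idx, cpgs.size - 1)] - start < L) & \
                  (cpgs[np.minimum(idx, cpgs.size - 1)] >= start)
        np.add.at(true_cov, np.minimum(idx, cpgs.size - 1)[covered], 1)
        diff = meas.values[0] - true_cov
        se = diff.std(ddof=1) / np.sqrt(diff.size)
        assert abs(diff.mean()) <= 2 * se + 1e-9


class TestCollapse:
    def _cov(self, cols, positions, n_sub=20, seed=0):
        rng = np.random.default_rng(seed)
        V = np.column_stack(cols)
        return CoverageMatrix(values=V, chrom_code=np.zeros(V.shape[1], np.int16),
                              positions=np.asarray(positions, np.int64),
                              chrom_names=["chr1"], subjects=[f"S{i}" for i in range(V.shape[0])])

    def test_identical_columns_merge(self):
        rng = np.random.default_rng(1)
        x = rng.random(20)
        sites, mat = cov.collapse_adjacent_cpgs(self._cov([x, x], [100, 150]), 0.9, 500)
        assert len(sites) == 1
        assert sites["n_cpgs"].iloc[0] == 2
        assert np.allclose(mat[:, 0], x)

    def test_independent_columns_stay_single(self):
        rng = np.random.default_rng(2)
        c = self._cov([rng.random(50), rng.random(50)], [100, 150])
        sites, _ = cov.collapse_adjacent_cpgs(c, 0.9, 500)
        assert len(sites) == 2

    def test_gap_blocks_merge(self):
        rng = np.random.default_rng(3)
        x = rng.random(20)
        sites, _ = cov.collapse_adjacent_cpgs(self._cov([x, x], [100, 800]), 0.9, 500)
        assert len(sites) == 2

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(4)
        n_sub, blocks = 40, [3, 2, 4]
        cols, pos, p = [], [], 1000
        for b in blocks:
            base = rng.random(n_sub)
            for _ in range(b):
                cols.append(base + rng.normal(0, 0.01, n_sub))
                pos.append(p)
                p += 120
            p += 30_000  # break correlation AND gap between blocks
        sites, mat = cov.collapse_adjacent_cpgs(self._cov(cols, pos), 0.9, 500)
        assert sites["n_cpgs"].tolist() == blocks
        V = np.column_stack(cols)
        lo = 0
        for k, b in enumerate(blocks):
            assert np.allclose(mat[:, k], V[:, lo:lo + b].mean(axis=1))
            lo += b

    def test_zero_variance_column_is_singleton(self):
        rng = np.random.default_rng(5)
        x = rng.random(20)
        c = self._cov([x, np.zeros(20), x], [100, 150, 200])
        sites, _ = cov.collapse_adjacent_cpgs(c, 0.9, 500)
        assert len(sites) == 3


class TestBackgroundFilter:
    def test_percentile_matches_sort_oracle(self):
        vals = np.random.default_rng(6).permutation(np.arange(1, 1001)).astype(float)
        # linear-interpolation percentile oracle: sorted index arithmetic
        srt = np.sort(vals)
        h = 0.975 * (len(vals) - 1)
        oracle = srt[int(h)] + (h - int(h)) * (srt[int(h) + 1] - srt[int(h)])
        assert np.percentile(vals, 97.5) == pytest.approx(oracle)

    def test_threshold_strictly_greater(self, small_ref):
        """A site whose mean equals the threshold exactly is dropped."""
        sites = pd.DataFrame({"site": ["a", "b"], "chrom": ["chr1"] * 2,
                              "start": [100, 300], "end": [150, 350],
                              "passed_background_filter": True, "masked": False})
        mat = np.array([[1.0, 2.0]] * 4)
        reads = make_reads([], [], subjects=["S0", "S1", "S2", "S3"])
        model = FragmentSizeModel(survival=np.ones(101), read_len=50)
        out, thr = cov.background_filter(
            sites, mat, reads, model, small_ref.cpg_positions, small_ref.lengths,
            n_background=500, seed=1)
        assert thr == 0.0
        # zero reads -> background 0; mean 1.0 and 2.0 both pass (strict >)
        assert out["passed_background_filter"].all()
        out2, _ = cov.background_filter(
            sites, mat * 0.0, reads, model, small_ref.cpg_positions,
            small_ref.lengths, n_background=500, seed=1)
        assert not out2["passed_background_filter"].any()  # mean == threshold == 0

    def test_background_loci_avoid_cpgs(self, small_ref):
        bg = cov.sample_background_loci(small_ref.cpg_positions, small_ref.lengths,
                                        non_cpg_gap=400, n_background=2000, seed=2)
        for chrom, loci in bg.items():
            cpg = small_ref.cpg_positions[chrom]
            for p in loci[:200]:
                i = np.searchsorted(cpg, p)
                near = min(abs(int(cpg[min(i, cpg.size - 1)]) - int(p)),
                           abs(int(p) - int(cpg[max(i - 1, 0)])))
                assert near >= 400


class TestMasks:
    def _sites(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df.insert(0, "site", [f"s{i}" for i in range(len(df))])
        df["masked"] = False
        return df

    def test_subtelomeric_masked(self):
        s = self._sites([("chr1", 500_000, 500_100)])
        out = cov.apply_region_masks(s, {"chr1": (40_000_000, 41_000_000)},
                                     {"chr1": 100_000_000})
        assert out["masked"].iloc[0]  # within 1 Mb of the start

    def test_interior_site_retained(self):
        s = self._sites([("chr1", 20_000_000, 20_000_100)])
        out = cov.apply_region_masks(s, {"chr1": (40_000_000, 41_000_000)},
                                     {"chr1": 100_000_000})
        assert not out["masked"].iloc[0]

    def test_matches_bruteforce_overlap_oracle(self):
        rng = np.random.default_rng(7)
        L, peri, subtel = 50_000_000, 5_000_000, 1_000_000
        cen = (24_000_000, 25_000_000)
        mask = (np.array([10_000_000, 35_000_000]),
                np.array([10_050_000, 35_200_000]))
        starts = rng.integers(0, L - 200, 400)
        s = self._sites([("chr1", int(x), int(x) + 150) for x in starts])
        out = cov.apply_region_masks(s, {"chr1": cen}, {"chr1": L},
                                     {"chr1": mask}, peri=peri, subtel=subtel)
        for _, r in out.iterrows():
            a, b = r["start"], r["end"]
            expect = (a < subtel or b > L - subtel or
                      (a < cen[1] + peri and b > cen[0] - peri) or
                      any(a < me and b > ms for ms, me in zip(*mask)))
            assert r["masked"] == expect
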