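"""FRiP, peak counts, stitching, region scoring and the super cutoff."""

import numpy as np
import pytest

from occuqc import enrichment, filters, simulate
from occuqc.model import GenomicInterval

from conftest import make_tagset, random_intervals, random_tags


def brute_stitch(peaks, gap):
    """Union-find merge oracle: peaks in one region iff chained gaps <= gap."""
    parent = list(range(len(peaks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(peaks):
        for j, b in enumerate(peaks):
            if i < j and a.chrom == b.chrom:
                lo, hi = (a, b) if a.start <= b.start else (b, a)
                if hi.start - lo.end <= gap or hi.start < lo.end:
                    parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(peaks):
        groups.setdefault(find(i), []).append(p)
    return sorted(
        (g[0].chrom, min(p.start for p in g), max(p.end for p in g), len(g))
        for g in groups.values())


class TestFrip:
    def test_hand_construction(self):
        peaks = [GenomicInterval("chr1", 1000, 2000)]
        tags = [("chr1", 1000 + i, "+", 50) for i in range(5)]
        tags += [("chr1", 5000 + i, "+", 50) for i in range(95)]
        assert enrichment.compute_frip(make_tagset(tags, {"chr1": 10_000}),
                                       peaks) == pytest.approx(0.05)

    def test_no_peaks_zero(self):
        ts = make_tagset([("chr1", 5, "+", 50)])
        assert enrichment.compute_frip(ts, []) == 0.0

    def test_all_inside_one(self):
        ts = make_tagset([("chr1", 100 + i, "-", 50) for i in range(10)],
                         {"chr1": 1000})
        assert enrichment.compute_frip(
            ts, [GenomicInterval("chr1", 50, 500)]) == 1.0

    def test_overlapping_peaks_not_double_counted(self):
        ts = make_tagset([("chr1", 100, "+", 50), ("chr1", 900, "+", 50)],
                         {"chr1": 1000})
        overlapping = [GenomicInterval("chr1", 50, 150),
                       GenomicInterval("chr1", 80, 200)]
        assert enrichment.compute_frip(ts, overlapping) == pytest.approx(0.5)

    def test_matches_membership_oracle(self, rng, toy_genome):
        for _ in range(10):
            tags = random_tags(rng, 100, toy_genome)
            peaks = random_intervals(rng, 10, toy_genome)
            got = enrichment.compute_frip(make_tagset(tags, toy_genome), peaks)
            expected = sum(
                any(p.contains_point(c, pos) for p in peaks)
                for c, pos, _, _ in tags) / len(tags)
            assert got == pytest.approx(expected)


class TestPeakCounts:
    def test_counts(self):
        peaks = [GenomicInterval("chr1", i * 100, i * 100 + 50)
                 for i in range(12)]
        assert enrichment.count_peaks(peaks) == 12
        assert enrichment.count_normalized_peaks(None) is None
        assert enrichment.count_normalized_peaks(peaks[:3]) == 3

    def test_blacklisted_peaks_excluded_upstream(self, rng, toy_genome):
        peaks = random_intervals(rng, 10, toy_genome)
        bl = [peaks[0], peaks[3], peaks[7]]
        kept = filters.filter_peaks_blacklist(peaks, bl)
        assert enrichment.count_peaks(kept) == 7


class TestStitching:
    def test_gap_merges(self):
        peaks = [GenomicInterval("chr1", 100, 200),
                 GenomicInterval("chr1", 250, 350)]
        rs = enrichment.stitch_peaks(peaks, 12_500)
        (r,) = rs.regions
        assert (r.interval.start, r.interval.end, r.member_peaks) == (100, 350, 2)

    def test_gap_too_small_keeps_separate(self):
        peaks = [GenomicInterval("chr1", 100, 200),
                 GenomicInterval("chr1", 250, 350)]
        assert enrichment.stitch_peaks(peaks, 10).n_regions == 2

    def test_negative_gap_errors(self):
        with pytest.raises(ValueError):
            enrichment.stitch_peaks([], -1)

    def test_matches_union_find_oracle(self, rng, toy_genome):
        for gap in (0, 500, 5_000):
            peaks = random_intervals(rng, 50, toy_genome)
            rs = enrichment.stitch_peaks(peaks, gap)
            got = sorted((r.interval.chrom, r.interval.start, r.interval.end,
                          r.member_peaks) for r in rs.regions)
            assert got == brute_stitch(peaks, gap)
            assert sum(r.member_peaks for r in rs.regions) == len(peaks)

    def test_idempotent(self, rng, toy_genome):
        peaks = random_intervals(rng, 40, toy_genome)
        once = enrichment.stitch_peaks(peaks, 1_000)
        twice = enrichment.stitch_peaks(once.intervals(), 1_000)
        assert [(r.interval.start, r.interval.end) for r in once.regions] == \
               [(r.interval.start, r.interval.end) for r in twice.regions]

    def test_monotone_in_gap(self, rng, toy_genome):
        peaks = random_intervals(rng, 60, toy_genome)
        counts = [enrichment.stitch_peaks(peaks, g).n_regions
                  for g in (0, 100, 1_000, 10_000, 100_000)]
        assert counts == sorted(counts, reverse=True)


class TestScoring:
    def test_tpm_arithmetic(self):
        tags = [("chr1", 100 + i, "+", 50) for i in range(100)]
        tags += [("chr1", 50_000 + i, "+", 50) for i in range(900)]
        ts = make_tagset(tags, {"chr1": 100_000})
        rs = enrichment.stitch_peaks([GenomicInterval("chr1", 0, 1_000)], 0)
        enrichment.score_regions(rs, ts)
        assert rs.regions[0].signal == pytest.approx(100 / 1_000 * 1e6)

    def test_control_subtraction_floor(self):
        ts = make_tagset([("chr1", 10, "+", 50)], {"chr1": 1000})
        ctrl = make_tagset([("chr1", 10, "+", 50), ("chr1", 11, "+", 50)],
                           {"chr1": 1000})
        rs = enrichment.stitch_peaks([GenomicInterval("chr1", 0, 100)], 0)
        enrichment.score_regions(rs, ts, ctrl)
        assert rs.regions[0].signal == 0.0

    def test_rank_depends_only_on_signal(self, rng, toy_genome):
        peaks = random_intervals(rng, 20, toy_genome)
        tags = random_tags(rng, 2_000, toy_genome)
        ts = make_tagset(tags, toy_genome)
        rs1 = enrichment.stitch_peaks(peaks, 100)
        enrichment.score_regions(rs1, ts)
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        rs2 = enrichment.stitch_peaks(shuffled, 100)
        enrichment.score_regions(rs2, ts)
        key = lambda r: (r.interval.chrom, r.interval.start)
        assert [(key(r), r.rank) for r in sorted(rs1.regions, key=key)] == \
               [(key(r), r.rank) for r in sorted(rs2.regions, key=key)]


class TestCutoff:
    def test_quadratic_curve_tangent(self):
        n = 501
        s = (np.arange(n) / (n - 1)) ** 2 * 1_000.0
        cutoff, is_super = enrichment.find_cutoff(s)
        # dy/dx = 2x = 1 at x = 0.5 -> cutoff at 0.25 of max
        assert cutoff == pytest.approx(250.0, abs=1_000 / (n - 1))
        assert is_super.sum() == (s > cutoff).sum()

    def test_linear_curve_no_supers(self):
        s = np.linspace(0.0, 10.0, 100)
        cutoff, is_super = enrichment.find_cutoff(s)
        assert is_super.sum() == 0

    def test_single_outlier_is_super(self):
        sig, truth = simulate.simulate_region_signals(
            n_regions=100, outlier_factor=50, seed=9)
        order = np.argsort(sig)
        cutoff, is_super = enrichment.find_cutoff(sig[order])
        assert is_super.sum() == 1
        assert (is_super == truth[order]).all()

    def test_no_outliers_small_top_tail(self):
        """Noise-only signals: the tangent rule calls only a small top
        tail (the quantile curve's slope crosses 1 near z ~ +1), never a
        majority, and no designed outliers exist."""
        sig, truth = simulate.simulate_region_signals(
            n_regions=100, outlier_factor=1, seed=9)
        assert not truth.any()
        _, is_super = enrichment.find_cutoff(np.sort(sig))
        assert is_super.sum() < 20

    def test_all_equal_warns_zero_supers(self):
        cutoff, is_super = enrichment.find_cutoff(np.full(10, 3.0))
        assert cutoff == 3.0 and is_super.sum() == 0

    def test_matches_brute_slope_scan(self, rng):
        for _ in range(20):
            s = np.sort(rng.gamma(2.0, 1.0, size=int(rng.integers(5, 40))))
            if s[0] == s[-1]:
                continue
            cutoff, is_super = enrichment.find_cutoff(s)
            n = s.size
            y = (s - s[0]) / (s[-1] - s[0])
            x = np.arange(n) / (n - 1)
            slopes = [(y[i + 1] - y[i]) * (n - 1) for i in range(n - 1)]
            if not any(sl > 1 for sl in slopes):
                assert is_super.sum() == 0
            else:
                idx = min(range(n), key=lambda i: y[i] - x[i])
                assert cutoff == s[idx]
                assert is_super.sum() == int((s > s[idx]).sum())


class TestSRatio:
    def test_ratio(self):
        rs = enrichment.StitchedRegionSet(
            regions=[enrichment.StitchedRegion(
                GenomicInterval("chr1", i * 10, i * 10 + 5), 1,
                is_super=i >= 8) for i in range(10)],
            stitch_gap=0)
        assert enrichment.s_ratio(rs) == pytest.approx(0.2)

    def test_empty_missing(self):
        rs = enrichment.StitchedRegionSet(regions=[], stitch_gap=0)
        assert enrichment.s_ratio(rs) is None

    def test_never_all_super_on_scored_data(self):
        peaks = simulate.simulate_peaks(seed=13)
        tags, _ = simulate.simulate_tags(peaks=peaks, n_fragments=20_000,
                                         seed=13)
        rs = enrichment.stitch_and_classify(peaks, tags)
        assert 0 < rs.n_super < rs.n_regions
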