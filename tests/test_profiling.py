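"""Promoter/metagene coverage matrices and peak annotation."""

import numpy as np
import pytest

from occuqc import profiling
from occuqc.model import GeneModel, GenomicInterval, OccuqcError

from conftest import make_tagset, random_intervals


def gene(gid, chrom, strand, start, end):
    return GeneModel(gid, chrom, strand,
                     GenomicInterval(chrom, start, end, strand=strand,
                                     name=gid))


class TestPromoterMatrix:
    def test_flat_input_flat_bins(self):
        # one tag every 10 bp: every full bin holds the same density
        tags = [("chr1", p, "+", 50) for p in range(0, 100_000, 10)]
        ts = make_tagset(tags, {"chr1": 100_000})
        g = gene("g1", "chr1", "+", 50_000, 60_000)
        m = profiling.promoter_matrix(ts, [g], 2_000, 50, mode="point")
        row = m.values[0]
        assert np.nanmax(row) == pytest.approx(np.nanmin(row))

    def test_delta_at_tss_center_bin(self):
        ts = make_tagset([("chr1", 50_000, "+", 50)] * 7, {"chr1": 100_000})
        g = gene("g1", "chr1", "+", 50_000, 60_000)
        m = profiling.promoter_matrix(ts, [g], 2_000, 50, mode="point")
        row = m.values[0]
        nonzero = np.flatnonzero(np.nan_to_num(row))
        assert list(nonzero) == [40]  # first bin of the downstream half

    def test_strand_flip_mirrors(self):
        """Tags 100 bp downstream of the TSS land in the same bin for a
        + gene and the mirrored − gene."""
        size = {"chr1": 100_000}
        gp = gene("gp", "chr1", "+", 50_000, 60_000)
        tsp = make_tagset([("chr1", 50_125, "+", 50)], size)
        gm = gene("gm", "chr1", "-", 40_000, 50_001)  # TSS at 50_000
        tsm = make_tagset([("chr1", 49_875, "+", 50)], size)
        mp = profiling.promoter_matrix(tsp, [gp], 2_000, 50, mode="point")
        mm = profiling.promoter_matrix(tsm, [gm], 2_000, 50, mode="point")
        assert np.flatnonzero(np.nan_to_num(mp.values[0])).tolist() == \
               np.flatnonzero(np.nan_to_num(mm.values[0])).tolist()

    def test_truncated_window_nan(self):
        ts = make_tagset([("chr1", 100, "+", 50)], {"chr1": 100_000})
        g = gene("g1", "chr1", "+", 500, 10_000)  # window past chrom start
        m = profiling.promoter_matrix(ts, [g], 2_000, 50, mode="point")
        assert np.isnan(m.values[0][:10]).all()

    def test_conservation_point_mode(self):
        """Bins of non-overlapping windows hold exactly the covered tags."""
        rng = np.random.default_rng(8)
        tags = [("chr1", int(p), "+", 50)
                for p in rng.integers(0, 100_000, 2_000)]
        ts = make_tagset(tags, {"chr1": 100_000})
        genes = [gene(f"g{i}", "chr1", "+", 10_000 + i * 20_000,
                      12_000 + i * 20_000) for i in range(4)]
        m = profiling.promoter_matrix(ts, genes, 2_000, 50, mode="point")
        # counts back from densities: density * bin_bp * total/1e6
        counts = np.nansum(m.values) * 50 * ts.n_tags / 1e6
        expected = sum(
            1 for _, p, _, _ in ts.iter_tags()
            if any(g.tss - 2_000 <= p < g.tss + 2_000 for g in genes))
        assert counts == pytest.approx(expected)


class TestMetageneMatrix:
    def test_uniform_tags_flat_profile(self):
        # evenly spaced tags aligned with bin edges: profile exactly flat
        tags = [("chr1", p, "+", 50) for p in range(0, 1_000_000, 10)]
        ts = make_tagset(tags, {"chr1": 1_000_000})
        genes = [gene(f"g{i}", "chr1", "+", 100_000 + i * 80_000,
                      120_000 + i * 80_000) for i in range(8)]
        m = profiling.metagene_matrix(ts, genes, 100, 2_000, 50, mode="point")
        prof = profiling.average_profile(m)
        assert np.max(prof) / np.min(prof) < 1.2
        np.testing.assert_allclose(prof, prof[0])

    def test_body_only_tags_empty_flanks(self):
        g = gene("g1", "chr1", "+", 50_000, 60_000)
        tags = [("chr1", p, "+", 50) for p in range(50_000, 60_000, 100)]
        ts = make_tagset(tags, {"chr1": 1_000_000})
        m = profiling.metagene_matrix(ts, [g], 100, 2_000, 50, mode="point")
        row = m.values[0]
        assert np.nansum(row[:40]) == 0 and np.nansum(row[-40:]) == 0
        assert np.nansum(row[40:140]) > 0

    def test_length_fair_normalization(self):
        """Doubling gene length under uniform per-bp coverage leaves body
        densities unchanged."""
        size = {"chr1": 1_000_000}
        tags = [("chr1", p, "+", 50) for p in range(0, 1_000_000, 10)]
        ts = make_tagset(tags, size)
        short = gene("s", "chr1", "+", 100_000, 110_000)
        long = gene("l", "chr1", "+", 400_000, 420_000)
        m = profiling.metagene_matrix(ts, [short, long], 100, 2_000, 50,
                                      mode="point")
        body = slice(40, 140)
        np.testing.assert_allclose(m.values[0][body], m.values[1][body],
                                   rtol=1e-6)

    def test_short_gene_skipped(self):
        ts = make_tagset([("chr1", 10, "+", 50)], {"chr1": 10_000})
        tiny = gene("t", "chr1", "+", 100, 150)
        ok = gene("ok", "chr1", "+", 1_000, 9_000)
        m = profiling.metagene_matrix(ts, [tiny, ok], 100, 500, 50,
                                      mode="point")
        assert m.row_ids == ["ok"]

    def test_strand_mirror_symmetry(self):
        """Mirroring all coordinates and strands leaves rows unchanged."""
        L = 200_000
        rng = np.random.default_rng(11)
        pos = rng.integers(0, L, 5_000)
        tags = [("chr1", int(p), "+", 50) for p in pos]
        ts = make_tagset(tags, {"chr1": L})
        g = gene("g", "chr1", "+", 60_000, 80_000)
        mirror_tags = [("chr1", L - 1 - int(p), "-", 50) for p in pos]
        mts = make_tagset(mirror_tags, {"chr1": L})
        mg = gene("g", "chr1", "-", L - 80_000, L - 60_000)
        m1 = profiling.metagene_matrix(ts, [g], 50, 1_000, 50, mode="point")
        m2 = profiling.metagene_matrix(mts, [mg], 50, 1_000, 50, mode="point")
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)


class TestAverageProfile:
    def test_single_row_identity(self):
        m = profiling.CoverageMatrix(["g"], ["a", "b"],
                                     np.array([[1.0, 3.0]]))
        np.testing.assert_allclose(profiling.average_profile(m), [1.0, 3.0])

    def test_two_rows_mean(self):
        m = profiling.CoverageMatrix(["a", "b"], ["x", "y"],
                                     np.array([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(profiling.average_profile(m), [1.0, 1.0])

    def test_nan_excluded_from_column(self):
        m = profiling.CoverageMatrix(["a", "b"], ["x"],
                                     np.array([[np.nan], [4.0]]))
        np.testing.assert_allclose(profiling.average_profile(m), [4.0])

    def test_empty_errors(self):
        m = profiling.CoverageMatrix([], [], np.zeros((0, 0)))
        with pytest.raises(OccuqcError):
            profiling.average_profile(m)

    def test_tss_enriched_rows_peak_at_tss(self):
        rng = np.random.default_rng(21)
        size = {"chr1": 2_000_000}
        genes = [gene(f"g{i}", "chr1", "+", 10_000 + i * 19_000,
                      25_000 + i * 19_000) for i in range(100)]
        tags = []
        for g in genes:
            tags += [("chr1", int(g.tss + d), "+", 50)
                     for d in rng.normal(0, 100, 50)]
        ts = make_tagset(tags, size)
        m = profiling.promoter_matrix(ts, genes, 2_000, 50, mode="point")
        prof = profiling.average_profile(m)
        peak_bin = int(np.nanargmax(prof))
        assert abs(peak_bin - 40) <= 2


class TestAnnotatePeaks:
    def _genes(self):
        return [gene("g1", "chr1", "+", 10_000, 20_000),
                gene("g2", "chr1", "-", 50_000, 60_000)]

    def test_promoter_category(self):
        dist = profiling.annotate_peaks(
            [GenomicInterval("chr1", 9_500, 9_800)], self._genes(),
            1_000, 10_000)
        assert dist.counts["promoter"] == 1

    def test_gene_body_precedence(self):
        dist = profiling.annotate_peaks(
            [GenomicInterval("chr1", 15_000, 15_500)], self._genes(),
            1_000, 10_000)
        assert dist.counts["gene_body"] == 1 and dist.counts["promoter"] == 0

    def test_window_then_intergenic(self):
        # [2000, 2100) overlaps only g1's TSS-centric window [0, 20000)
        dist = profiling.annotate_peaks(
            [GenomicInterval("chr1", 2_000, 2_100),
             GenomicInterval("chr1", 900_000, 900_100)],
            self._genes(), 1_000, 10_000)
        assert dist.counts["gene_window"] == 1
        assert dist.counts["intergenic"] == 1

    def test_nearest_gene_distance(self):
        dist = profiling.annotate_peaks(
            [GenomicInterval("chr1", 30_000, 30_100),
             GenomicInterval("chr1", 9_900, 10_100)],
            self._genes(), 1_000, 10_000)
        rows = dist.per_peak
        assert rows.iloc[0]["nearest_gene"] == "g1"
        assert rows.iloc[0]["distance"] == 30_050 - 10_000
        assert rows.iloc[1]["distance"] == 0  # TSS inside peak

    def test_matches_allpairs_oracle_and_sums(self, rng, toy_genome):
        genes = [gene(f"g{i}", c, s, a, b) for i, (c, s, a, b) in enumerate(
            [("chr1", "+", 5_000, 15_000), ("chr1", "-", 30_000, 42_000),
             ("chr1", "+", 70_000, 90_000), ("chr2", "-", 10_000, 22_000),
             ("chr2", "+", 40_000, 55_000), ("chr2", "+", 60_000, 75_000),
             ("chr1", "-", 55_000, 63_000), ("chr2", "-", 28_000, 33_000),
             ("chr1", "+", 92_000, 99_000), ("chr2", "+", 1_000, 4_000)])]
        peaks = random_intervals(rng, 50, toy_genome)
        ph, wh = 1_000, 10_000
        dist = profiling.annotate_peaks(peaks, genes, ph, wh)
        expected = {c: 0 for c in profiling.CATEGORIES}
        for p in peaks:
            cats = set()
            for g in genes:
                if g.chrom != p.chrom:
                    continue
                if p.overlaps(GenomicInterval(
                        g.chrom, max(0, g.tss - ph), g.tss + ph)):
                    cats.add("promoter")
                if p.overlaps(g.body):
                    cats.add("gene_body")
                if p.overlaps(GenomicInterval(
                        g.chrom, max(0, g.tss - wh), g.tss + wh)):
                    cats.add("gene_window")
            for cat in ("promoter", "gene_body", "gene_window", "intergenic"):
                if cat == "intergenic" or cat in cats:
                    expected[cat] += 1
                    break
        assert dist.counts == expected
        assert dist.total == len(peaks)

    def test_no_genes_errors(self):
        with pytest.raises(OccuqcError):
            profiling.annotate_peaks([], [], 1_000, 10_000)
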