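"""Interval algebra, coordinate conventions and flat-file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relochip.genome_core import (
    BedParseError,
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    ReadSet,
    merge_intervals,
    overlap_query,
    read_bed,
    read_gene_table,
    write_bed,
)
from tests.conftest import random_intervals

interval_st = st.builds(
    lambda chrom, start, length, strand: GenomicInterval(chrom, start, start + length, strand),
    chrom=st.sampled_from(["chr1", "chr2", "chrX"]),
    start=st.integers(0, 10**6),
    length=st.integers(1, 10**4),
    strand=st.sampled_from(["+", "-", "."]),
)


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 1)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 1, "x")

    def test_half_open_boundary_never_overlaps(self):
        a = GenomicInterval("chr1", 100, 200)
        assert not a.overlaps(GenomicInterval("chr1", 200, 300))
        assert a.overlaps(GenomicInterval("chr1", 199, 300))
        assert not a.overlaps(GenomicInterval("chr2", 100, 200))


class TestGeneModel:
    def test_strand_aware_tss_tes(self):
        plus = GeneModel("g", "chr1", "+", 100, 200)
        minus = GeneModel("g", "chr1", "-", 100, 200)
        assert (plus.tss, plus.tes) == (100, 199)
        assert (minus.tss, minus.tes) == (199, 100)

    def test_exon_outside_span_rejected(self):
        with pytest.raises(ValueError):
            GeneModel(
                "g", "chr1", "+", 100, 200,
                exons=(GenomicInterval("chr1", 150, 250, "+"),),
            )

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            GeneModel(
                "g", "chr1", "+", 100, 200,
                exons=(
                    GenomicInterval("chr1", 100, 150, "+"),
                    GenomicInterval("chr1", 140, 200, "+"),
                ),
            )


class TestBedIO:
    def test_three_column_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        (iv,) = read_bed(p)
        assert (iv.chrom, iv.start, iv.end, iv.strand) == ("chr1", 100, 200, ".")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert read_bed(p) == []
        write_bed([], p)
        assert p.read_text() == ""

    def test_strand_preserved(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t0\t10\tpeak\t5\t-\n")
        (iv,) = read_bed(p)
        assert iv.strand == "-" and iv.name == "peak" and iv.score == 5.0

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\nchr1\t5\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_start_ge_end_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t10\n")
        with pytest.raises(BedParseError):
            read_bed(p)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(interval_st, max_size=100))
    def test_round_trip_identity(self, tmp_path_factory, intervals):
        p = tmp_path_factory.mktemp("bed") / "rt.bed"
        write_bed(intervals, p)
        back = read_bed(p)
        assert [(i.chrom, i.start, i.end, i.strand) for i in back] == [
            (i.chrom, i.start, i.end, i.strand) for i in intervals
        ]
        # second round trip is byte-identical
        p2 = tmp_path_factory.mktemp("bed") / "rt2.bed"
        write_bed(back, p2)
        assert p.read_text() == p2.read_text()


class TestGeneTable:
    GFF = (
        "##gff-version 3\n"
        "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        "chr1\t.\texon\t101\t150\t.\t+\t.\tParent=g1\n"
        "chr1\t.\texon\t171\t200\t.\t+\t.\tParent=g1\n"
        "chr1\t.\tgene\t101\t200\t.\t-\t.\tID=g2\n"
    )

    def test_gff3_coordinate_conversion(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(self.GFF)
        genes = read_gene_table(p, "gff3")
        g1 = next(g for g in genes if g.gene_id == "g1")
        assert (g1.tx_start, g1.tx_end) == (100, 200)
        assert [(e.start, e.end) for e in g1.exons] == [(100, 150), (170, 200)]

    def test_minus_strand_tss(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(self.GFF)
        g2 = next(g for g in read_gene_table(p, "gff3") if g.gene_id == "g2")
        assert g2.tss == 199

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "chr1\t.\tgene\t1\t10\t.\t+\t.\tID=g1\n"
            "chr1\t.\tgene\t21\t30\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_gene_table(p, "gff3")

    def test_exon_outside_span_rejected(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n"
            "chr1\t.\texon\t50\t120\t.\t+\t.\tParent=g1\n"
        )
        with pytest.raises(ValueError, match="outside"):
            read_gene_table(p, "gff3")

    def test_fixture_gff3_gene_and_exon_counts(self, tmp_path):
        lines = ["##gff-version 3"]
        expected = {}
        for i in range(5):
            gid = f"g{i}"
            start = 1000 * i + 1
            lines.append(f"chr1\t.\tgene\t{start}\t{start + 500}\t.\t+\t.\tID={gid}")
            n_ex = i + 1
            expected[gid] = n_ex
            for j in range(n_ex):
                s = start + 50 * j
                lines.append(f"chr1\t.\texon\t{s}\t{s + 20}\t.\t+\t.\tParent={gid}")
        p = tmp_path / "five.gff3"
        p.write_text("\n".join(lines) + "\n")
        genes = read_gene_table(p, "gff3")
        assert len(genes) == 5
        assert {g.gene_id: len(g.exons) for g in genes} == expected


def bp_coverage(intervals, chroms=("chr1", "chr2"), size=110_000):
    cov = {c: np.zeros(size, dtype=bool) for c in chroms}
    for iv in intervals:
        cov[iv.chrom][iv.start : iv.end] = True
    return cov


class TestMergeIntervals:
    def test_empty(self):
        assert merge_intervals([]) == []

    def test_bookended_and_overlapping(self):
        ivs = [
            GenomicInterval("chr1", 0, 10),
            GenomicInterval("chr1", 5, 15),
            GenomicInterval("chr1", 20, 30),
        ]
        merged = merge_intervals(ivs)
        assert [(m.start, m.end) for m in merged] == [(0, 15), (20, 30)]

    def test_single_interval_identity(self):
        iv = GenomicInterval("chr1", 3, 9)
        (m,) = merge_intervals([iv])
        assert (m.chrom, m.start, m.end) == ("chr1", 3, 9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_coverage_preserved_vs_bitmap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, 200)
        merged = merge_intervals(ivs)
        before = bp_coverage(ivs)
        after = bp_coverage(merged)
        for c in before:
            assert np.array_equal(before[c], after[c])
        # disjointness and sortedness
        for a, b in zip(merged, merged[1:]):
            assert (a.chrom, a.start) <= (b.chrom, b.start)
            if a.chrom == b.chrom:
                assert a.end < b.start  # book-ended runs were merged too


class TestOverlapQuery:
    def test_simple_hit(self):
        idx = IntervalIndex([GenomicInterval("chr1", 150, 160)])
        assert len(overlap_query(idx, GenomicInterval("chr1", 100, 200))) == 1

    def test_half_open_boundary_is_no_hit(self):
        idx = IntervalIndex([GenomicInterval("chr1", 200, 300)])
        assert overlap_query(idx, GenomicInterval("chr1", 100, 200)) == []

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_quadratic_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        A = random_intervals(rng, 500)
        B = random_intervals(rng, 500)
        idx = IntervalIndex(B)
        for a in A:
            fast = {(h.chrom, h.start, h.end) for h in overlap_query(idx, a)}
            brute = {
                (b.chrom, b.start, b.end)
                for b in B
                if b.chrom == a.chrom and max(a.start, b.start) < min(a.end, b.end)
            }
            assert fast == brute

    def test_order_deterministic_by_start(self):
        B = [
            GenomicInterval("chr1", 300, 400),
            GenomicInterval("chr1", 100, 500),
            GenomicInterval("chr1", 200, 250),
        ]
        idx = IntervalIndex(B)
        hits = overlap_query(idx, GenomicInterval("chr1", 0, 1000))
        assert [h.start for h in hits] == [100, 200, 300]


class TestReadSet:
    def test_total_and_sorting(self):
        from relochip.genome_core import ReadRecord

        rs = ReadSet(
            {"chr1": [ReadRecord(500, "+"), ReadRecord(100, "-")], "chr2": [ReadRecord(7, "+")]},
            label="x",
        )
        assert rs.total_reads == 3
        assert rs.starts("chr1").tolist() == [100, 500]

    def test_fragment_midpoints_strand_aware(self):
        from relochip.genome_core import ReadRecord

        rs = ReadSet({"chr1": [ReadRecord(100, "+"), ReadRecord(1000, "-")]})
        mids = rs.fragment_midpoints("chr1", 450)
        assert mids.tolist() == [325, 775]

    def test_sam_text_ingestion(self, tmp_path):
        from relochip.genome_core import read_sam

        sam = tmp_path / "reads.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:chr1\tLN:10000\n"
            "r1\t0\tchr1\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "r2\t16\tchr1\t201\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"  # unmapped, skipped
        )
        rs = read_sam(sam, label="x")
        assert rs.total_reads == 2
        # SAM is 1-based: r1 5' at 100 (+); r2 reverse, 5' at end-1 = 249
        assert rs.starts("chr1").tolist() == [100, 249]
        assert rs.is_forward("chr1").tolist() == [True, False]

    def test_bed_round_trip_preserves_five_prime_ends(self, tmp_path):
        from relochip.genome_core import ReadRecord, read_bed

        rs = ReadSet(
            {"chr1": [ReadRecord(100, "+"), ReadRecord(1000, "-"), ReadRecord(999_990, "-")]},
            read_length=50,
        )
        p = tmp_path / "reads.bed"
        rs.to_bed(p)
        back = ReadSet.from_intervals(read_bed(p), read_length=50)
        assert back.starts("chr1").tolist() == rs.starts("chr1").tolist()
        assert back.is_forward("chr1").tolist() == rs.is_forward("chr1").tolist()
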