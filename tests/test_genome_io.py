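import numpy as np
import pytest

from regmk.genome_io import (
    AnnotationSet,
    Gene,
    GenomicInterval,
    Stratum,
    assign_acr_to_gene,
    assign_stratum,
    complement,
    intergenic_space,
    label_strata,
    merge_intervals,
    read_intervals,
    read_strata_table,
    write_bed,
    write_strata_table,
)


class TestReadIntervals:
    def test_bed_line_is_zero_based_half_open(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chrY\t100\t200\tacr1\n")
        (itv,) = read_intervals(path, "BED")
        assert (itv.chrom, itv.start, itv.end, itv.label) == ("chrY", 100, 200, "acr1")

    def test_narrowpeak_keeps_first_four_columns(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chrX\t10\t60\tpeak1\t100\t.\t5.1\t4.2\t3.3\t25\n")
        (itv,) = read_intervals(path, "narrowPeak")
        assert (itv.start, itv.end, itv.label) == (10, 60, "peak1")

    def test_gff_converted_to_internal_convention(self, tmp_path):
        path = tmp_path / "a.gff"
        path.write_text("chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;Parent=x\n")
        (itv,) = read_intervals(path, "GFF")
        assert (itv.start, itv.end, itv.label) == (100, 200, "g1")

    @pytest.mark.parametrize(
        "content",
        ["chr1\t50\t50\tempty\n", "chr1\t60\t50\tbad\n", "chr1\tfifty\t60\n", "chr1\t50\n"],
    )
    def test_malformed_line_error_names_line_number(self, tmp_path, content):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t10\tok\n" + content)
        with pytest.raises(ValueError, match=r":2:|line"):
            read_intervals(path, "BED")

    def test_round_trip_is_identity(self, tmp_path, rng):
        intervals = []
        for i in range(50):
            start = int(rng.integers(0, 10_000))
            intervals.append(
                GenomicInterval("chr1", start, start + int(rng.integers(1, 500)), f"iv{i}")
            )
        intervals.sort(key=lambda x: (x.chrom, x.start, x.end))
        path = tmp_path / "rt.bed"
        write_bed(intervals, path)
        back = read_intervals(path, "BED")
        assert [(i.chrom, i.start, i.end, i.label) for i in back] == [
            (i.chrom, i.start, i.end, i.label) for i in intervals
        ]


class TestIntergenicSpace:
    def _annotations(self, genes=(), repeats=(), acrs=(), length=1000):
        return AnnotationSet(
            genes=[Gene("chr1", s, e, f"g{i}") for i, (s, e) in enumerate(genes)],
            repeats=[GenomicInterval("chr1", s, e) for s, e in repeats],
            acrs=[GenomicInterval("chr1", s, e) for s, e in acrs],
            chrom_lengths={"chr1": length},
        )

    def test_complement_of_overlapping_annotations(self):
        ann = self._annotations(genes=[(100, 200)], repeats=[(150, 300)], acrs=[(400, 450)])
        out = intergenic_space(ann, "chr1")
        assert [(i.start, i.end) for i in out] == [(0, 100), (300, 400), (450, 1000)]

    def test_no_annotations_gives_whole_chromosome(self):
        out = intergenic_space(self._annotations(), "chr1")
        assert [(i.start, i.end) for i in out] == [(0, 1000)]

    def test_fully_tiled_chromosome_gives_empty(self):
        ann = self._annotations(genes=[(0, 600)], repeats=[(500, 1000)])
        assert intergenic_space(ann, "chr1") == []

    def test_unknown_chromosome_raises(self):
        with pytest.raises(KeyError):
            intergenic_space(self._annotations(), "chrZ")

    def test_never_overlaps_any_annotation(self, rng):
        for _ in range(20):
            genes = []
            repeats = []
            acrs = []
            for _ in range(int(rng.integers(0, 15))):
                s = int(rng.integers(0, 900))
                itv = (s, s + int(rng.integers(1, 120)))
                [genes, repeats, acrs][int(rng.integers(0, 3))].append(itv)
            ann = self._annotations(genes=genes, repeats=repeats, acrs=acrs)
            out = intergenic_space(ann, "chr1")
            annotated = (
                [g.interval for g in ann.genes] + ann.repeats + ann.acrs
            )
            for free in out:
                assert all(not free.overlaps(a) for a in annotated)
            # disjoint and sorted
            for a, b in zip(out, out[1:]):
                assert a.end <= b.start


class TestAssignAcrToGene:
    def test_nearest_tss_within_bound_wins(self):
        acr = GenomicInterval("chr1", 9_750, 10_250, "acr")  # midpoint 10 kb
        genes = [Gene("chr1", 20_000, 21_000, "geneA"), Gene("chr1", 70_000, 71_000, "geneB")]
        assert assign_acr_to_gene([acr], genes)["acr"] == "geneA"

    def test_beyond_50kb_is_unassigned(self):
        acr = GenomicInterval("chr1", 0, 100, "acr")  # midpoint 50
        genes = [Gene("chr1", 55_050, 56_000, "geneA")]
        assert assign_acr_to_gene([acr], genes)["acr"] is None

    def test_equidistant_tie_broken_by_lower_tss_then_id(self):
        acr = GenomicInterval("chr1", 9_900, 10_100, "acr")  # midpoint 10_000
        genes = [Gene("chr1", 12_000, 13_000, "geneB"), Gene("chr1", 7_001, 8_001, "geneA", "-")]
        # TSS: geneB at 12_000 (+), geneA at 8_000 (-); both 2 kb away
        assert assign_acr_to_gene([acr], genes)["acr"] == "geneA"
        same_tss = [Gene("chr1", 12_000, 13_000, "b"), Gene("chr1", 12_000, 13_500, "a")]
        assert assign_acr_to_gene([acr], same_tss)["acr"] == "a"

    def test_edge_anchor_uses_nearest_edge(self):
        acr = GenomicInterval("chr1", 0, 80_000, "wide")
        genes = [Gene("chr1", 100_000, 101_000, "geneA")]
        # midpoint (40 kb) is 60 kb from TSS -> unassigned; edge is 20 kb away
        assert assign_acr_to_gene([acr], genes, anchor="midpoint")["wide"] is None
        assert assign_acr_to_gene([acr], genes, anchor="edge")["wide"] == "geneA"

    def test_agrees_with_brute_force_scan(self, rng):
        genes = [
            Gene("chr1", int(s), int(s) + 100, f"g{i}", "+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(sorted(rng.integers(0, 1_000_000, size=60)))
        ]
        acrs = [
            GenomicInterval("chr1", int(s), int(s) + 200, f"a{i}")
            for i, s in enumerate(rng.integers(0, 999_000, size=120))
        ]
        result = assign_acr_to_gene(acrs, genes)
        for acr in acrs:
            candidates = [
                (abs(acr.midpoint - g.tss), g.tss, g.gene_id)
                for g in genes
                if abs(acr.midpoint - g.tss) <= 50_000
            ]
            expected = min(candidates)[2] if candidates else None
            assert result[acr.label] == expected


class TestStrata:
    def test_assignment_pure_function_of_position(self, tmp_path):
        bounds = [
            GenomicInterval("chrXY", 0, 100, stratum=Stratum.S1),
            GenomicInterval("chrXY", 100, 200, stratum=Stratum.S2),
        ]
        assert assign_stratum("chrXY", 50, bounds) is Stratum.S1
        assert assign_stratum("chrXY", 100, bounds) is Stratum.S2
        assert assign_stratum("chrXY", 500, bounds) is Stratum.NA
        assert assign_stratum("chrZ", 50, bounds) is Stratum.NA
        path = tmp_path / "strata.tsv"
        write_strata_table(bounds, path)
        back = read_strata_table(path)
        assert [b.stratum for b in back] == [Stratum.S1, Stratum.S2]

    def test_label_strata_uses_midpoint(self):
        bounds = [GenomicInterval("chrXY", 0, 100, stratum=Stratum.S3)]
        (labelled,) = label_strata([GenomicInterval("chrXY", 90, 130)], bounds)
        assert labelled.stratum is Stratum.NA  # midpoint 110 outside S3
        (labelled,) = label_strata([GenomicInterval("chrXY", 50, 130)], bounds)
        assert labelled.stratum is Stratum.S3


from hypothesis import given, settings
from hypothesis import strategies as st


@given(
    spans=st.lists(
        st.tuples(st.integers(0, 950), st.integers(1, 50)), min_size=0, max_size=40
    )
)
@settings(derandomize=True, max_examples=100)
def test_merge_and_complement_partition_the_chromosome(spans):
    intervals = [GenomicInterval("c", s, s + w) for s, w in spans]
    merged = merge_intervals(intervals)
    comp = complement(intervals, "c", 1000)
    covered = sum(len(i) for i in merged) + sum(len(i) for i in comp)
    assert covered == 1000
    for a in merged:
        assert all(not a.overlaps(b) for b in comp)
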