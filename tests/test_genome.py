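"""Annotation parsing, TSS conventions and peak classification."""

import pytest

from acetylink.genome import (
    AnnotationError,
    Peak,
    classify_feature,
    classify_proximal_distal,
    intron_ordinal,
    parse_annotation,
    peak_gene_distance,
    read_narrowpeak,
    write_gtf,
)

from conftest import make_gene


GTF_LINES = [
    # + strand gene, exons (100,200) and (300,400) in 1-based inclusive GTF
    'chr1\tsrc\tgene\t100\t400\t.\t+\t.\tgene_id "gA";',
    'chr1\tsrc\ttranscript\t100\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA_t1";',
    'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA_t1";',
    'chr1\tsrc\texon\t300\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA_t1";',
    # same exon structure on the - strand
    'chr1\tsrc\tgene\t1100\t1400\t.\t-\t.\tgene_id "gB";',
    'chr1\tsrc\texon\t1100\t1200\t.\t-\t.\tgene_id "gB"; transcript_id "gB_t1";',
    'chr1\tsrc\texon\t1300\t1400\t.\t-\t.\tgene_id "gB"; transcript_id "gB_t1";',
]


@pytest.fixture
def gtf_file(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text("\n".join(GTF_LINES) + "\n")
    return p


class TestParseAnnotation:
    def test_strand_aware_tss(self, gtf_file):
        ann = parse_annotation(gtf_file)
        # + strand: 5'-most base; GTF 100 -> internal 99
        assert ann.genes["gA"].tss == 99
        # - strand: the 3'-coordinate end boundary; GTF 1400 -> internal 1399
        assert ann.genes["gB"].tss == 1399

    def test_coordinates_converted_to_half_open(self, gtf_file):
        ann = parse_annotation(gtf_file)
        assert ann.genes["gA"].canonical_transcript().exons == [(99, 200), (299, 400)]

    def test_canonical_transcript_is_longest(self):
        g = make_gene("g", "chr1", "+", [(0, 300)], tid="t_short")
        long_tx = make_gene("g", "chr1", "+", [(0, 250), (400, 650)], tid="t_long")
        g.transcripts["t_long"] = long_tx.transcripts["t_long"]
        g.end = 650
        # exonic lengths 300 vs 500 -> the 500 bp transcript wins
        assert g.canonical_transcript().id == "t_long"
        assert g.tss == 0

    def test_canonical_tie_breaks_lexicographically(self):
        g = make_gene("g", "chr1", "+", [(0, 300)], tid="t_b")
        other = make_gene("g", "chr1", "+", [(500, 800)], tid="t_a")
        g.transcripts["t_a"] = other.transcripts["t_a"]
        g.end = 800
        assert g.canonical_transcript().id == "t_a"

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(GTF_LINES[0] + "\nchr1\tonly_three_fields\toops\n")
        with pytest.raises(AnnotationError, match="line 2"):
            parse_annotation(p)

    def test_exon_outside_transcript_bounds_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\ts\ttranscript\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\ts\texon\t100\t300\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(AnnotationError, match="outside transcript"):
            parse_annotation(p)

    def test_roundtrip_preserves_tss(self, gtf_file, tmp_path):
        ann = parse_annotation(gtf_file)
        out = tmp_path / "rt.gtf"
        write_gtf(ann, out)
        again = parse_annotation(out)
        assert again.tss == ann.tss


class TestProximalDistal:
    def test_tss_inside_peak_is_proximal(self, toy_annotation):
        peak = Peak("p", "chr1", 50, 300, 150)  # contains TSS 99
        assert classify_proximal_distal(peak, toy_annotation) == "proximal"

    def test_far_peak_is_distal(self, toy_annotation):
        peak = Peak("p", "chr1", 50_000, 50_500, 50_200)
        assert classify_proximal_distal(peak, toy_annotation) == "distal"

    def test_boundary_distance_exactly_1kb_is_proximal(self):
        # TSS at 1099, peak covering [0, 100): last base 99, distance 1000
        ann_gene = make_gene("g", "chr1", "+", [(1099, 1500)])
        from acetylink.genome import GenomeAnnotation

        ann = GenomeAnnotation({"chr1": 10_000}, {"g": ann_gene})
        peak = Peak("p", "chr1", 0, 100, 50)
        assert classify_proximal_distal(peak, ann) == "proximal"
        # one base further is distal
        far = make_gene("g", "chr1", "+", [(1100, 1500)])
        ann2 = GenomeAnnotation({"chr1": 10_000}, {"g": far})
        assert classify_proximal_distal(peak, ann2) == "distal"

    def test_unannotated_chromosome_is_distal(self, toy_annotation):
        peak = Peak("p", "chr2", 100, 200, 150)
        assert classify_proximal_distal(peak, toy_annotation) == "distal"

    def test_invariant_to_gene_order(self, toy_annotation):
        from acetylink.genome import GenomeAnnotation

        peak = Peak("p", "chr1", 9000, 9500, 9200)
        reordered = GenomeAnnotation(
            dict(toy_annotation.chrom_sizes),
            dict(reversed(list(toy_annotation.genes.items()))),
        )
        assert classify_proximal_distal(peak, toy_annotation) == classify_proximal_distal(
            peak, reordered
        )


class TestClassifyFeature:
    def test_summit_near_tss_is_promoter(self, toy_annotation):
        peak = Peak("p", "chr1", 0, 600, 120)
        assert classify_feature(peak, toy_annotation).kind == "promoter-TSS"

    def test_summit_in_exon(self, toy_annotation):
        # exon (10099,10200) of the minus gene; avoid the promoter window
        # around its TSS 10399 by using a position 1 kb+ away -> impossible
        # here, so use a dedicated gene with long exons
        from acetylink.genome import GenomeAnnotation

        g = make_gene("g", "chr1", "+", [(5000, 8000), (9000, 9500)])
        ann = GenomeAnnotation({"chr1": 100_000}, {"g": g})
        peak = Peak("p", "chr1", 7000, 7400, 7200)  # 2.2 kb from TSS 5000
        assert classify_feature(peak, ann).kind == "exon"

    def test_summit_in_intron_with_ordinal(self):
        from acetylink.genome import GenomeAnnotation

        g = make_gene("g", "chr1", "+", [(5000, 5200), (8000, 8200), (9000, 9200)])
        ann = GenomeAnnotation({"chr1": 100_000}, {"g": g})
        peak = Peak("p", "chr1", 8400, 8800, 8500)  # in the second intron
        label = classify_feature(peak, ann)
        assert label.kind == "intron" and label.intron_ordinal == 2

    def test_far_summit_is_intergenic(self, toy_annotation):
        peak = Peak("p", "chr1", 500_000, 500_500, 500_200)
        assert classify_feature(peak, toy_annotation).kind == "intergenic"

    def test_classification_is_total(self, small_bundle):
        cfg, b = small_bundle
        kinds = {"promoter-TSS", "exon", "intron", "intergenic"}
        for m in b["consensus_peaks"][:100]:
            assert classify_feature(m.as_peak(), b["annotation"]).kind in kinds


class TestIntronOrdinal:
    def test_plus_strand_first_intron(self):
        g = make_gene("g", "chr1", "+", [(99, 200), (299, 400)])
        t = g.canonical_transcript()
        assert intron_ordinal(250, t) == 1

    def test_minus_strand_counts_from_tss_side(self):
        # same genomic intron, but on - the TSS is at the 400-side
        g = make_gene("g", "chr1", "-", [(99, 200), (299, 400)])
        t = g.canonical_transcript()
        assert intron_ordinal(250, t) == 1
        g3 = make_gene("g3", "chr1", "-", [(0, 100), (200, 300), (400, 500)])
        t3 = g3.canonical_transcript()
        # genomic intron (300,400) is nearest the - strand TSS at 499
        assert intron_ordinal(350, t3) == 1
        assert intron_ordinal(150, t3) == 2

    def test_exonic_position_has_no_ordinal(self):
        g = make_gene("g", "chr1", "+", [(99, 200), (299, 400)])
        assert intron_ordinal(150, g.canonical_transcript()) is None

    def test_single_exon_transcript_never_intronic(self):
        g = make_gene("g", "chr1", "+", [(0, 1000)])
        assert intron_ordinal(500, g.canonical_transcript()) is None

    def test_ordinal_within_bounds(self, small_bundle):
        cfg, b = small_bundle
        for g in list(b["annotation"].genes.values())[:50]:
            t = g.canonical_transcript()
            for s, e in t.introns():
                k = intron_ordinal((s + e) // 2, t)
                assert k is not None and 1 <= k <= len(t.exons) - 1


class TestPeakGeneDistance:
    def test_summit_to_tss(self):
        g = make_gene("g", "chr1", "+", [(1_400_000, 1_400_500)])
        peak = Peak("p", "chr1", 499_000, 501_000, 500_000)
        assert peak_gene_distance(peak, g) == 900_000

    def test_zero_when_summit_at_tss(self):
        g = make_gene("g", "chr1", "+", [(500, 900)])
        peak = Peak("p", "chr1", 400, 700, 500)
        assert peak_gene_distance(peak, g) == 0

    def test_cross_chromosome_is_an_error(self):
        g = make_gene("g", "chr2", "+", [(500, 900)])
        peak = Peak("p", "chr1", 400, 700, 500)
        with pytest.raises(ValueError, match="different chromosomes"):
            peak_gene_distance(peak, g)


class TestNarrowPeakIO:
    def test_summit_from_offset_column(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t600\tpk1\t0\t.\t7.5\t-1\t-1\t50\n")
        peaks = read_narrowpeak(p, sample="s1")
        assert peaks[0].summit == 150 and peaks[0].signal == 7.5

    def test_bed6_falls_back_to_midpoint(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t600\tpk1\t0\t.\n")
        assert read_narrowpeak(p)[0].summit == 350
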