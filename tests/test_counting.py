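"""Gene-level counting: the assignment cascade, modes and strandedness."""

import io

import pytest

from xseq import (
    CountOptions,
    assign_unit,
    build_feature_index,
    count_alignments,
    count_file,
    parse_sam_line,
    read_gff,
    read_sam,
)

# Two genes on "+" of chr1: G1 exons [100,200) and [400,500); G2 exon
# [450,600) overlapping G1's second exon. G3 on "-" exon [1000,1100).
ANNOTATION = "".join(
    f'chr1\tt\texon\t{s}\t{e}\t.\t{strand}\t.\tgene_id "{g}";\n'
    for g, strand, s, e in [
        ("G1", "+", 101, 200),
        ("G1", "+", 401, 500),
        ("G2", "+", 451, 600),
        ("G3", "-", 1001, 1100),
    ]
)


def sam(pos, cigar="50M", flag=0, mapq=42, name="r", tags=""):
    qlen = sum(
        int(n)
        for n, op in __import__("re").findall(r"(\d+)([A-Z=])", cigar)
        if op in "MIS=X"
    )
    line = (
        f"{name}\t{flag}\tchr1\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
        f"{'A' * qlen}\t{'I' * qlen}"
    )
    if tags:
        line += "\t" + tags
    return parse_sam_line(line)


def index_for(stranded="no"):
    opts = CountOptions(stranded=stranded, log_every=0)
    feats = read_gff(io.StringIO(ANNOTATION))
    return build_feature_index(feats, opts)


class TestFeatureIndex:
    def test_overlap_region_carries_both_genes(self):
        index, gene_ids = index_for("no")
        from xseq import GenomicInterval

        assert gene_ids == ["G1", "G2", "G3"]
        assert index.union(GenomicInterval("chr1", 120, 130)) == {"G1"}
        assert index.union(GenomicInterval("chr1", 460, 480)) == {"G1", "G2"}
        assert index.union(GenomicInterval("chr1", 520, 580)) == {"G2"}

    def test_non_matching_type_ignored(self):
        text = ANNOTATION + 'chr1\tt\tCDS\t1\t50\t.\t+\t.\tgene_id "GX";\n'
        _, gene_ids = build_feature_index(
            read_gff(io.StringIO(text)), CountOptions(stranded="no")
        )
        assert "GX" not in gene_ids

    def test_missing_id_attribute_is_an_error(self):
        bad = "chr1\tt\texon\t1\t50\t.\t+\t.\tfoo bar;\n"
        with pytest.raises(ValueError, match="gene_id"):
            build_feature_index(
                read_gff(io.StringIO(bad)), CountOptions(stranded="no")
            )

    def test_empty_annotation_gives_empty_index(self):
        index, gene_ids = build_feature_index(
            read_gff(io.StringIO("")), CountOptions(stranded="no")
        )
        assert gene_ids == []

    def test_strandless_feature_rejected_when_stranded(self):
        text = 'chr1\tt\texon\t1\t50\t.\t.\t.\tgene_id "G";\n'
        with pytest.raises(ValueError, match="strand"):
            build_feature_index(
                read_gff(io.StringIO(text)), CountOptions(stranded="yes")
            )


class TestAssignmentCascade:
    def setup_method(self):
        self.index, _ = index_for("no")
        self.opts = CountOptions(stranded="no", log_every=0)

    def assign(self, unit, **kw):
        opts = CountOptions(stranded="no", log_every=0, **kw)
        return assign_unit(unit, self.index, opts)

    def test_read_inside_one_gene(self):
        assert self.assign(sam(120)) == "G1"

    def test_read_straddling_two_genes_is_ambiguous(self):
        assert self.assign(sam(460)) == "__ambiguous"

    def test_read_half_outside_depends_on_mode(self):
        # 50M starting at base 175 (1-based): [174,224) half in G1's exon
        unit = sam(175)
        assert self.assign(unit, mode="union") == "G1"
        assert self.assign(unit, mode="intersection-strict") == "__no_feature"
        assert self.assign(unit, mode="intersection-nonempty") == "G1"

    def test_intergenic_read(self):
        assert self.assign(sam(700)) == "__no_feature"

    def test_unaligned_routes_first(self):
        a = parse_sam_line("r\t4\t*\t0\t0\t*\t*\t0\t0\tAC\tII")
        assert self.assign(a) == "__not_aligned"

    def test_multimapper_via_nh_tag(self):
        assert self.assign(sam(120, tags="NH:i:2")) == "__alignment_not_unique"
        assert self.assign(sam(120, tags="NH:i:1")) == "G1"

    def test_multimapper_via_secondary_flag(self):
        assert self.assign(sam(120, flag=0x100)) == "__alignment_not_unique"

    def test_low_mapq_routed_after_multimap_check(self):
        assert self.assign(sam(120, mapq=3)) == "__too_low_aQual"
        assert (
            self.assign(sam(120, mapq=3, tags="NH:i:5"))
            == "__alignment_not_unique"
        )
        assert self.assign(sam(120, mapq=3), min_aqual=0) == "G1"

    def test_spliced_read_skips_gene_between_exons(self):
        # 25M200N25M from 150: covers G1 exon1 end and exon2 start, N over
        # the intron; union gives G1 only
        unit = sam(151, cigar="25M226N25M")
        assert self.assign(unit) == "G1"

    def test_pair_both_mates_one_gene_counts_once(self):
        m1 = parse_sam_line(
            "p\t99\tchr1\t105\t42\t20M\t=\t150\t65\t"
            + "A" * 20 + "\t" + "I" * 20
        )
        m2 = parse_sam_line(
            "p\t147\tchr1\t150\t42\t20M\t=\t105\t-65\t"
            + "A" * 20 + "\t" + "I" * 20
        )
        assert self.assign((m1, m2)) == "G1"

    def test_pair_with_one_aligned_mate_uses_it(self):
        m1 = parse_sam_line(
            "p\t73\tchr1\t105\t42\t20M\t*\t0\t0\t"
            + "A" * 20 + "\t" + "I" * 20
        )
        m2 = parse_sam_line(
            "p\t133\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20
        )
        assert self.assign((m1, m2)) == "G1"
        assert self.assign((None, m2)) == "__not_aligned"

    def test_read_on_unannotated_chromosome_is_no_feature(self):
        line = "r\t0\tchrZ\t10\t42\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII"
        assert self.assign(parse_sam_line(line)) == "__no_feature"


class TestStrandedness:
    def test_sense_read_counts_antisense_does_not(self):
        index, _ = index_for("yes")
        opts_yes = CountOptions(stranded="yes", log_every=0)
        opts_rev = CountOptions(stranded="reverse", log_every=0)
        sense = sam(120)  # "+" read over "+" gene G1
        anti = sam(120, flag=0x10)
        assert assign_unit(sense, index, opts_yes) == "G1"
        assert assign_unit(anti, index, opts_yes) == "__no_feature"
        assert assign_unit(anti, index, opts_rev) == "G1"
        assert assign_unit(sense, index, opts_rev) == "__no_feature"

    def test_mate_roles_flip_the_required_strand(self):
        index, _ = index_for("yes")
        opts = CountOptions(stranded="yes", log_every=0)
        # second mate on "-" over a "+" gene is sense-consistent
        m2 = parse_sam_line(
            "p\t147\tchr1\t120\t42\t20M\t=\t105\t-35\t"
            + "A" * 20 + "\t" + "I" * 20
        )
        assert assign_unit((None, m2), index, opts) == "G1"


class TestCountFileProperties:
    @pytest.mark.parametrize("mode", ["union", "intersection-strict",
                                      "intersection-nonempty"])
    @pytest.mark.parametrize("stranded", ["yes", "no", "reverse"])
    def test_conservation_identity(self, small_fixture_parsed, mode, stranded):
        fx, feats, alns = small_fixture_parsed
        opts = CountOptions(
            mode=mode, stranded=stranded, paired=True, log_every=0
        )
        table = count_alignments(iter(alns), feats, opts)
        assert table.total_units == fx.truth.n_units

    def test_mode_ordering_on_fixture(self, small_fixture_parsed):
        """A strict-mode gene assignment never changes gene in laxer modes."""
        from xseq.counting import build_feature_index
        from xseq import pair_alignments_with_buffer

        fx, feats, alns = small_fixture_parsed
        base = dict(stranded="no", paired=True, log_every=0)
        index, _ = build_feature_index(
            iter(feats), CountOptions(**base)
        )
        for pair in pair_alignments_with_buffer(iter(alns)):
            strict = assign_unit(pair, index, CountOptions(mode="intersection-strict", **base))
            nonempty = assign_unit(pair, index, CountOptions(mode="intersection-nonempty", **base))
            union = assign_unit(pair, index, CountOptions(mode="union", **base))
            if not strict.startswith("__"):
                assert nonempty == strict
                assert union in (strict, "__ambiguous")
            if not nonempty.startswith("__"):
                assert union in (nonempty, "__ambiguous")

    def test_shuffled_sam_gives_identical_table(self, small_fixture_parsed):
        import random

        fx, feats, alns = small_fixture_parsed
        opts = CountOptions(paired=True, log_every=0)
        t1 = count_alignments(iter(alns), feats, opts)
        shuffled = alns[:]
        random.Random(0).shuffle(shuffled)
        t2 = count_alignments(iter(shuffled), feats, opts)
        assert t1.as_dict() == t2.as_dict()

    def test_empty_sam_counts_nothing(self):
        opts = CountOptions(stranded="no", log_every=0)
        table = count_file(io.StringIO(""), io.StringIO(ANNOTATION), opts)
        assert table.total_units == 0
        assert set(table.counts.values()) == {0}

    def test_output_order_genes_then_specials(self):
        opts = CountOptions(stranded="no", log_every=0)
        table = count_file(io.StringIO(""), io.StringIO(ANNOTATION), opts)
        sink = io.StringIO()
        table.write(sink)
        lines = sink.getvalue().splitlines()
        assert lines[:3] == ["G1\t0", "G2\t0", "G3\t0"]
        assert [l.split("\t")[0] for l in lines[3:]] == [
            "__no_feature",
            "__ambiguous",
            "__too_low_aQual",
            "__not_aligned",
            "__alignment_not_unique",
        ]

    def test_truth_recovery_on_small_fixture(self, small_fixture_parsed):
        fx, feats, alns = small_fixture_parsed
        opts = CountOptions(
            mode="union", stranded="yes", paired=True, log_every=0
        )
        table = count_alignments(iter(alns), feats, opts)
        assert table.as_dict() == fx.truth.table("union", "yes")

    def test_skip_flagged_option_drops_marked_records(self):
        dup = sam(120, flag=0x400)
        ok = sam(120, name="r2")
        feats = list(read_gff(io.StringIO(ANNOTATION)))
        default = count_alignments(
            iter([dup, ok]), feats, CountOptions(stranded="no", log_every=0)
        )
        skipping = count_alignments(
            iter([dup, ok]), feats,
            CountOptions(stranded="no", skip_flagged=True, log_every=0),
        )
        assert default.counts["G1"] == 2
        assert skipping.counts["G1"] == 1
        assert skipping.total_units == 1


def test_invalid_options_rejected():
    with pytest.raises(ValueError):
        CountOptions(mode="bogus")
    with pytest.raises(ValueError):
        CountOptions(stranded="maybe")
    with pytest.raises(ValueError):
        CountOptions(min_aqual=-1)
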