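"""CIGAR decomposition, SAM record parsing, and mate pairing."""

import io
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xseq import (
    pair_alignments_with_buffer,
    parse_cigar,
    parse_sam_line,
    read_sam,
    write_sam_line,
)

_CONSUMES_QUERY = set("MIS=X")
_CONSUMES_REF = set("MDN=X")


def cigar_oracle(tokens, ref_start):
    """Per-base reference walk: covered positions and cursor totals."""
    covered = []
    q = 0
    r = ref_start
    for size, op in tokens:
        if op in "M=XD":
            covered.extend(range(r, r + size))
        if op in _CONSUMES_QUERY:
            q += size
        if op in _CONSUMES_REF:
            r += size
    runs = []
    for p in covered:
        if runs and runs[-1][1] == p:
            runs[-1][1] = p + 1
        else:
            runs.append([p, p + 1])
    return q, r, [tuple(x) for x in runs]


class TestParseCigar:
    def test_spliced_alignment(self):
        ops = parse_cigar("20M100N30M", 1000, 50, "1", "+")
        assert [(o.op, o.query_from, o.query_to) for o in ops] == [
            ("M", 0, 20),
            ("N", 20, 20),
            ("M", 20, 50),
        ]
        assert [(o.ref_iv.start, o.ref_iv.end) for o in ops] == [
            (1000, 1020),
            (1020, 1120),
            (1120, 1150),
        ]

    def test_soft_clip_consumes_query_only(self):
        ops = parse_cigar("5S10M", 0, 15, "1", "+")
        assert (ops[0].query_from, ops[0].query_to) == (0, 5)
        assert ops[0].ref_iv.length == 0 and ops[0].ref_iv.start == 0
        assert (ops[1].ref_iv.start, ops[1].ref_iv.end) == (0, 10)

    def test_single_block(self):
        (op,) = parse_cigar("10M", 7, 10, "1", "+")
        assert (op.ref_iv.start, op.ref_iv.end) == (7, 17)

    def test_star_is_empty(self):
        assert parse_cigar("*", 0, None, "1", "+") == []

    def test_errors_name_the_token(self):
        with pytest.raises(ValueError, match="'Q'|10Q"):
            parse_cigar("10Q", 0, 10, "1", "+")
        with pytest.raises(ValueError, match="malformed"):
            parse_cigar("10M5", 0, 10, "1", "+")
        with pytest.raises(ValueError, match="consumes"):
            parse_cigar("5M", 0, 10, "1", "+")

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.tuples(
                st.integers(1, 50), st.sampled_from("MIDNSHP=X")
            ),
            min_size=1,
            max_size=8,
        ),
        st.integers(0, 1000),
    )
    def test_cursor_continuity_against_oracle(self, tokens, ref_start):
        cigar = "".join(f"{n}{op}" for n, op in tokens)
        qlen, rend, runs = cigar_oracle(tokens, ref_start)
        ops = parse_cigar(cigar, ref_start, qlen, "c", "+")
        for a, b in zip(ops, ops[1:]):
            assert b.query_from == a.query_to
            assert b.ref_iv.start == a.ref_iv.end
        assert ops[0].ref_iv.start == ref_start
        assert ops[-1].ref_iv.end == rend
        assert sum(o.query_to - o.query_from for o in ops) == qlen


SAM_LINE = (
    "r1\t0\tchr1\t100\t42\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII"
)


class TestParseSamLine:
    def test_plus_strand_and_coordinate_conversion(self):
        a = parse_sam_line(SAM_LINE)
        assert a.aligned
        assert a.iv.strand == "+"
        assert a.iv.start == 99 and a.iv.end == 109
        assert a.aQual == 42
        assert a.pe_which == "not_paired"

    def test_reverse_flag_sets_minus_strand(self):
        a = parse_sam_line(SAM_LINE.replace("r1\t0", "r1\t16"))
        assert a.iv.strand == "-"

    def test_unaligned_record(self):
        a = parse_sam_line("r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII")
        assert not a.aligned
        assert a.iv is None
        assert a.cigar == []

    def test_optional_fields_typed(self):
        a = parse_sam_line(SAM_LINE + "\tNH:i:3\tAS:f:1.5\tXX:Z:hi")
        assert a.optional_field("NH") == 3
        assert a.optional_field("AS") == 1.5
        assert a.optional_field("XX") == "hi"

    def test_malformed_lines_rejected(self):
        with pytest.raises(ValueError, match="fields"):
            parse_sam_line("r1\t0\tchr1")
        with pytest.raises(ValueError, match="non-numeric"):
            parse_sam_line(SAM_LINE.replace("\t100\t", "\tabc\t"))

    def test_pairing_flags_decoded(self):
        line = (
            "r1\t99\tchr1\t100\t42\t10M\t=\t300\t210\tACGTACGTAC\tIIIIIIIIII"
        )
        a = parse_sam_line(line)
        assert a.pe_which == "first"
        assert a.proper_pair
        assert a.mate_start.chrom == "chr1"
        assert a.mate_start.pos == 299
        assert a.mate_start.strand == "-"


class TestCoveredRefIntervals:
    @pytest.mark.parametrize(
        "cigar, pos, expected",
        [
            ("20M100N30M", 1001, [(1000, 1020), (1120, 1150)]),
            ("10M2D10M", 1, [(0, 22)]),
            ("10M", 1, [(0, 10)]),
            ("5S10M3I5M", 1, [(0, 15)]),
        ],
    )
    def test_footprint(self, cigar, pos, expected):
        qlen = sum(
            int(n)
            for n, op in __import__("re").findall(r"(\d+)([A-Z])", cigar)
            if op in "MIS=X"
        )
        seq = "A" * qlen
        line = f"r\t0\tc\t{pos}\t40\t{cigar}\t*\t0\t0\t{seq}\t{'I' * qlen}"
        a = parse_sam_line(line)
        assert [(i.start, i.end) for i in a.covered_ref_intervals()] == expected

    def test_unaligned_has_no_footprint(self):
        a = parse_sam_line("r\t4\t*\t0\t0\t*\t*\t0\t0\tAC\tII")
        with pytest.raises(ValueError):
            a.covered_ref_intervals()

    def test_random_cigars_match_reference_walk_oracle(self):
        rng = random.Random(99)
        for _ in range(500):
            tokens = [
                (rng.randint(1, 30), rng.choice("MMMM=XIDNS"))
                for _ in range(rng.randint(1, 6))
            ]
            qlen, _, runs = cigar_oracle(tokens, 500)
            if qlen == 0:
                continue
            cigar = "".join(f"{n}{op}" for n, op in tokens)
            seq = "A" * qlen
            line = (
                f"r\t0\tc\t501\t40\t{cigar}\t*\t0\t0\t{seq}\t{'I' * qlen}"
            )
            a = parse_sam_line(line)
            assert [
                (i.start, i.end) for i in a.covered_ref_intervals()
            ] == runs


class TestSamRoundTrip:
    @pytest.mark.parametrize(
        "line",
        [
            SAM_LINE,
            SAM_LINE + "\tNH:i:2\tXZ:Z:tag",
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII",
            "r2\t163\tchr2\t55\t7\t5M2N5M\t=\t200\t155\tACGTACGTAC\t*",
        ],
    )
    def test_parse_write_parse_identity(self, line):
        a = parse_sam_line(line)
        b = parse_sam_line(write_sam_line(a))
        assert b == a

    def test_fixture_sam_round_trips(self, small_fixture):
        for a in read_sam(io.StringIO(small_fixture.sam)):
            assert parse_sam_line(write_sam_line(a)) == a


def _make_pair(name, pos1, pos2, chrom="c"):
    l1 = (
        f"{name}\t99\t{chrom}\t{pos1}\t40\t10M\t=\t{pos2}\t20\t"
        f"{'A' * 10}\t{'I' * 10}"
    )
    l2 = (
        f"{name}\t147\t{chrom}\t{pos2}\t40\t10M\t=\t{pos1}\t-20\t"
        f"{'A' * 10}\t{'I' * 10}"
    )
    return parse_sam_line(l1), parse_sam_line(l2)


class TestPairing:
    def test_shuffled_pairs_all_join(self):
        rng = random.Random(7)
        records = []
        for i in range(200):
            records.extend(_make_pair(f"p{i}", 100 + i, 300 + i))
        rng.shuffle(records)
        pairs = list(pair_alignments_with_buffer(records))
        assert len(pairs) == 200
        assert all(a is not None and b is not None for a, b in pairs)
        assert all(
            a.pe_which == "first" and b.pe_which == "second" for a, b in pairs
        )

    def test_permutation_invariant_multiset(self):
        records = []
        for i in range(50):
            records.extend(_make_pair(f"p{i}", 10 + i, 500 + i))
        rng = random.Random(1)
        shuffled = records[:]
        rng.shuffle(shuffled)
        key = lambda pair: (pair[0].read.name, pair[0].iv.start)
        p1 = sorted(pair_alignments_with_buffer(records), key=key)
        p2 = sorted(pair_alignments_with_buffer(shuffled), key=key)
        assert [(a.read.name, b.read.name) for a, b in p1] == [
            (a.read.name, b.read.name) for a, b in p2
        ]

    def test_adjacent_mates_keep_buffer_at_one(self):
        records = []
        for i in range(30):
            records.extend(_make_pair(f"p{i}", 100 + i, 300 + i))
        # capacity 1 suffices when mates are adjacent
        pairs = list(pair_alignments_with_buffer(records, max_buffer_size=1))
        assert len(pairs) == 30

    def test_orphan_reported_with_absent_mate(self):
        records = list(_make_pair("p0", 100, 300))
        orphan_first, _ = _make_pair("lonely", 50, 700)
        records.append(orphan_first)
        pairs = list(pair_alignments_with_buffer(records))
        orphans = [p for p in pairs if None in p]
        assert len(pairs) == 2
        assert len(orphans) == 1
        assert orphans[0][0].read.name == "lonely"
        assert orphans[0][1] is None

    def test_multimapped_pairs_do_not_cross_join(self):
        a1, a2 = _make_pair("m", 100, 300)
        b1, b2 = _make_pair("m", 5000, 5200)
        pairs = list(pair_alignments_with_buffer([a1, b1, b2, a2]))
        assert len(pairs) == 2
        for first, second in pairs:
            assert first.mate_start.pos == second.iv.start

    def test_duplicate_pairing_key_is_an_error(self):
        a1, _ = _make_pair("d", 100, 300)
        a1b, _ = _make_pair("d", 100, 300)
        with pytest.raises(ValueError, match="pairing key"):
            list(pair_alignments_with_buffer([a1, a1b]))

    def test_buffer_capacity_enforced(self):
        firsts = [_make_pair(f"p{i}", 100 + i, 900 + i)[0] for i in range(10)]
        with pytest.raises(MemoryError):
            list(pair_alignments_with_buffer(firsts, max_buffer_size=5))

    def test_unpaired_records_pass_through(self):
        a = parse_sam_line(SAM_LINE)
        assert list(pair_alignments_with_buffer([a])) == [(a, None)]


def test_fixture_sam_agrees_with_pysam(small_fixture, tmp_path):
    """Independent cross-check of coordinates and flags via pysam."""
    pysam = pytest.importorskip("pysam")
    path = tmp_path / "reads.sam"
    path.write_text(small_fixture.sam)
    ours = list(read_sam(io.StringIO(small_fixture.sam)))
    theirs = list(pysam.AlignmentFile(str(path), "r"))
    assert len(ours) == len(theirs)
    for a, b in zip(ours, theirs):
        assert a.aligned == (not b.is_unmapped)
        assert a.read.name == b.query_name
        if not a.aligned:
            continue
        assert a.iv.chrom == b.reference_name
        assert a.iv.start == b.reference_start
        assert a.iv.end == b.reference_end
        assert a.iv.strand == ("-" if b.is_reverse else "+")
        assert a.aQual == b.mapping_quality
        assert [
            (i.start, i.end) for i in a.covered_ref_intervals()
        ] == b.get_blocks()
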