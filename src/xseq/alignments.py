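"""SAM alignment records with coordinate-resolved CIGAR operations.

A CIGAR string compactly describes how a read aligns to the reference;
each operation consumes query bases, reference bases, both, or neither.
:func:`parse_cigar` walks the string once, accumulating both cursors, so
every operation carries its half-open range in the read ("query") and its
:class:`~xseq.core.GenomicInterval` on the reference — gapped and clipped
alignments then need no special-casing downstream.

Paired-end SAM stores one fragment as two records that need not be
adjacent; :func:`pair_alignments_with_buffer` joins them by read name plus
mutual (position, mate-position) consistency, buffering records whose mate
has not yet been seen, so name- and position-sorted input work alike.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, TextIO

from .core import GenomicInterval, GenomicPosition, SequenceWithQualities

logger = logging.getLogger(__name__)

# SAM operation consumption table
_CONSUMES_QUERY = frozenset("MIS=X")
_CONSUMES_REF = frozenset("MDN=X")
_CIGAR_OPS = frozenset("MIDNSHP=X")
_CIGAR_TOKEN = re.compile(r"(\d+)([A-Za-z=])")

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_QC_FAIL = 0x200
FLAG_DUPLICATE = 0x400


@dataclass
class CigarOperation:
    """One CIGAR operation with its resolved query and reference ranges.

    ``query_from``/``query_to`` delimit the affected read bases (equal for
    operations that consume no query); ``ref_iv`` is the affected reference
    interval (zero-length for operations that consume no reference).
    """

    op: str
    size: int
    query_from: int
    query_to: int
    ref_iv: GenomicInterval

    def __str__(self) -> str:
        return (
            f"{self.size}{self.op} query[{self.query_from},{self.query_to}) "
            f"ref {self.ref_iv}"
        )


def parse_cigar(
    cigar_string: str,
    ref_start: int,
    query_length: int | None,
    chrom: str,
    strand: str = ".",
) -> list[CigarOperation]:
    """Decompose a CIGAR string into coordinate-resolved operations.

    Walks left to right keeping a query cursor and a reference cursor:
    M/=/X consume both, I/S consume query only, D/N consume reference only,
    H/P consume neither. ``"*"`` yields an empty list. When
    ``query_length`` is given, the query-consuming sizes must sum to it.
    """
    if cigar_string == "*":
        return []
    ops: list[CigarOperation] = []
    qpos = 0
    rpos = ref_start
    matched_to = 0
    for m in _CIGAR_TOKEN.finditer(cigar_string):
        if m.start() != matched_to:
            raise ValueError(
                f"malformed CIGAR {cigar_string!r} near "
                f"{cigar_string[matched_to:matched_to + 5]!r}"
            )
        matched_to = m.end()
        size = int(m.group(1))
        op = m.group(2)
        if op not in _CIGAR_OPS:
            raise ValueError(
                f"unknown CIGAR operation {op!r} in {cigar_string!r}"
            )
        if size <= 0:
            raise ValueError(
                f"non-positive CIGAR size in token {m.group(0)!r}"
            )
        dq = size if op in _CONSUMES_QUERY else 0
        dr = size if op in _CONSUMES_REF else 0
        ops.append(
            CigarOperation(
                op=op,
                size=size,
                query_from=qpos,
                query_to=qpos + dq,
                ref_iv=GenomicInterval(chrom, rpos, rpos + dr, strand),
            )
        )
        qpos += dq
        rpos += dr
    if matched_to != len(cigar_string):
        raise ValueError(
            f"malformed CIGAR {cigar_string!r} near "
            f"{cigar_string[matched_to:matched_to + 5]!r}"
        )
    if query_length is not None and qpos != query_length:
        raise ValueError(
            f"CIGAR {cigar_string!r} consumes {qpos} query bases but the "
            f"read is {query_length} bases long"
        )
    return ops


@dataclass
class SamAlignment:
    """One SAM alignment record.

    ``iv`` is None for unaligned records. ``pe_which`` is "first",
    "second" or "not_paired". ``optional_fields`` preserves tag order;
    values are typed (i → int, f → float, others → str).
    """

    read: SequenceWithQualities
    aligned: bool
    iv: GenomicInterval | None
    cigar: list[CigarOperation]
    aQual: int
    flags: int
    mate_start: GenomicPosition | None = None
    pe_which: str = "not_paired"
    optional_fields: dict[str, Any] = field(default_factory=dict)
    tlen: int = 0
    _opt_types: dict[str, str] = field(default_factory=dict, repr=False)
    _star_qual: bool = field(default=False, repr=False)

    @property
    def paired_end(self) -> bool:
        return bool(self.flags & FLAG_PAIRED)

    @property
    def proper_pair(self) -> bool:
        return bool(self.flags & FLAG_PROPER_PAIR)

    @property
    def mate_aligned(self) -> bool:
        return self.paired_end and not self.flags & FLAG_MATE_UNMAPPED

    @property
    def not_primary_alignment(self) -> bool:
        return bool(self.flags & FLAG_SECONDARY)

    @property
    def failed_platform_qc(self) -> bool:
        return bool(self.flags & FLAG_QC_FAIL)

    @property
    def pcr_or_optical_duplicate(self) -> bool:
        return bool(self.flags & FLAG_DUPLICATE)

    def optional_field(self, tag: str, default=None):
        return self.optional_fields.get(tag, default)

    def covered_ref_intervals(self) -> list[GenomicInterval]:
        """Maximal reference runs covered by M/=/X/D, split at N gaps.

        This is the read's counting footprint: small deletions (D) keep
        the run contiguous, intron skips (N) split it, and clips/insertions
        consume no reference so they never split anything.
        """
        if not self.aligned:
            raise ValueError(
                f"read {self.read.name!r} is unaligned: no reference footprint"
            )
        runs: list[list[int]] = []
        for op in self.cigar:
            if op.op not in "M=XD":
                continue
            if runs and runs[-1][1] == op.ref_iv.start:
                runs[-1][1] = op.ref_iv.end
            else:
                runs.append([op.ref_iv.start, op.ref_iv.end])
        assert self.iv is not None
        return [
            GenomicInterval(self.iv.chrom, s, e, self.iv.strand)
            for s, e in runs
        ]


def _parse_optional(fields: Iterable[str]) -> tuple[dict[str, Any], dict[str, str]]:
    values: dict[str, Any] = {}
    types: dict[str, str] = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) != 3:
            raise ValueError(f"malformed optional field {f!r}")
        tag, typ, raw = parts
        if typ == "i":
            values[tag] = int(raw)
        elif typ == "f":
            values[tag] = float(raw)
        else:
            values[tag] = raw
        types[tag] = typ
    return values, types


def parse_sam_line(line: str) -> SamAlignment:
    """Parse one SAM alignment line (not a header line) into a record.

    POS is converted to 0-based; the strand is "-" iff flag 0x10 is set.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise ValueError(
            f"SAM line has {len(fields)} fields, expected >= 11: "
            f"{line[:60]!r}"
        )
    qname, flag_s, rname, pos_s, mapq_s = fields[:5]
    cigar_s, rnext, pnext_s, tlen_s, seq, qual_s = fields[5:11]
    try:
        flag = int(flag_s)
        pos = int(pos_s)
        mapq = int(mapq_s)
        pnext = int(pnext_s)
        tlen = int(tlen_s)
    except ValueError:
        raise ValueError(
            f"non-numeric FLAG/POS/MAPQ/PNEXT/TLEN in SAM line for "
            f"{qname!r}"
        ) from None
    strand = "-" if flag & FLAG_REVERSE else "+"
    aligned = not flag & FLAG_UNMAPPED
    seq_str = "" if seq == "*" else seq
    star_qual = qual_s == "*"
    if star_qual:
        qual = [255] * len(seq_str)
    else:
        if len(qual_s) != len(seq_str):
            raise ValueError(
                f"SEQ/QUAL length mismatch for read {qname!r}"
            )
        qual = [ord(c) - 33 for c in qual_s]
    read = SequenceWithQualities(qname, seq_str, qual)
    if aligned:
        if rname == "*":
            raise ValueError(f"aligned read {qname!r} has RNAME '*'")
        cigar = parse_cigar(
            cigar_s, pos - 1, len(seq_str) or None, rname, strand
        )
        ref_len = sum(op.size for op in cigar if op.op in _CONSUMES_REF)
        iv = GenomicInterval(rname, pos - 1, pos - 1 + ref_len, strand)
    else:
        cigar = []
        iv = None
    mate_start = None
    if flag & FLAG_PAIRED and not flag & FLAG_MATE_UNMAPPED and rnext != "*":
        mate_chrom = rname if rnext == "=" else rnext
        mate_strand = "-" if flag & FLAG_MATE_REVERSE else "+"
        mate_start = GenomicPosition(mate_chrom, pnext - 1, mate_strand)
    if flag & FLAG_PAIRED:
        if flag & FLAG_FIRST and not flag & FLAG_SECOND:
            pe_which = "first"
        elif flag & FLAG_SECOND and not flag & FLAG_FIRST:
            pe_which = "second"
        else:
            pe_which = "unknown"
    else:
        pe_which = "not_paired"
    opt_values, opt_types = _parse_optional(fields[11:])
    return SamAlignment(
        read=read,
        aligned=aligned,
        iv=iv,
        cigar=cigar,
        aQual=mapq,
        flags=flag,
        mate_start=mate_start,
        pe_which=pe_which,
        optional_fields=opt_values,
        tlen=tlen,
        _opt_types=opt_types,
        _star_qual=star_qual,
    )


def _fmt_opt(tag: str, typ: str, value: Any) -> str:
    if typ == "f" and isinstance(value, float):
        return f"{tag}:f:{format(value, 'g')}"
    return f"{tag}:{typ}:{value}"


def write_sam_line(a: SamAlignment) -> str:
    """Serialize a record back to one SAM line (no trailing newline).

    Re-parsing the result reproduces all 11 mandatory fields and the
    optional fields. RNEXT is written as "=" when the mate shares the
    chromosome.
    """
    if a.aligned:
        assert a.iv is not None
        rname = a.iv.chrom
        pos = a.iv.start + 1
        cigar = "".join(f"{op.size}{op.op}" for op in a.cigar) or "*"
    else:
        rname, pos, cigar = "*", 0, "*"
    if a.mate_start is not None:
        rnext = (
            "="
            if a.aligned and a.mate_start.chrom == a.iv.chrom
            else a.mate_start.chrom
        )
        pnext = a.mate_start.pos + 1
    else:
        rnext, pnext = "*", 0
    seq = a.read.seq or "*"
    if a._star_qual or not a.read.qual:
        qual = "*"
    else:
        qual = "".join(chr(q + 33) for q in a.read.qual)
    fields = [
        a.read.name,
        str(a.flags),
        rname,
        str(pos),
        str(a.aQual),
        cigar,
        rnext,
        str(pnext),
        str(a.tlen),
        seq,
        qual,
    ]
    fields.extend(
        _fmt_opt(tag, a._opt_types.get(tag, "Z"), value)
        for tag, value in a.optional_fields.items()
    )
    return "\t".join(fields)


def read_sam(source) -> Iterator[SamAlignment]:
    """Yield alignment records from a text SAM stream; '@' headers skipped."""
    from .io import _as_stream

    stream = _as_stream(source)
    for lineno, line in enumerate(stream, 1):
        if not line.strip() or line.startswith("@"):
            continue
        try:
            yield parse_sam_line(line)
        except ValueError as exc:
            raise ValueError(f"SAM line {lineno}: {exc}") from None


def write_sam(
    alignments: Iterable[SamAlignment],
    sink: TextIO,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    if chrom_lengths:
        sink.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in chrom_lengths.items():
            sink.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
    for a in alignments:
        sink.write(write_sam_line(a) + "\n")


def _pos_key(a: SamAlignment):
    return (a.iv.chrom, a.iv.start) if a.aligned else None


def _mate_pos_key(a: SamAlignment):
    if a.mate_start is None:
        return None
    return (a.mate_start.chrom, a.mate_start.pos)


class PairOrphanError(ValueError):
    pass


def pair_alignments_with_buffer(
    records: Iterable[SamAlignment],
    max_buffer_size: int = 3_000_000,
) -> Iterator[tuple[SamAlignment | None, SamAlignment | None]]:
    """Join paired-end records into (first_mate, second_mate) tuples.

    Records are matched on read name, complementary first/second roles and
    mutually consistent (position, mate position) — the triple that keeps
    multiple alignments of the same pair from cross-joining. Input order is
    free: a pair is yielded when its second record arrives; records whose
    mate never arrives are yielded at the end as orphans, with None in the
    missing slot, and their count is logged.

    Records not flagged as paired pass straight through as
    ``(record, None)``. The buffer of outstanding mates is capped at
    ``max_buffer_size`` records; pathological input that exceeds it is an
    error rather than unbounded memory growth.
    """
    buffer: dict[tuple, SamAlignment] = {}
    peak = 0
    for a in records:
        if not a.paired_end:
            yield a, None
            continue
        if a.pe_which not in ("first", "second"):
            raise ValueError(
                f"paired record {a.read.name!r} has ambiguous first/second "
                "flags"
            )
        other_role = "second" if a.pe_which == "first" else "first"
        partner_key = (a.read.name, other_role, _mate_pos_key(a), _pos_key(a))
        mate = buffer.pop(partner_key, None)
        if mate is not None:
            yield (a, mate) if a.pe_which == "first" else (mate, a)
            continue
        own_key = (a.read.name, a.pe_which, _pos_key(a), _mate_pos_key(a))
        if own_key in buffer:
            raise ValueError(
                f"ill-formed input: a third record matches the pairing key "
                f"of read {a.read.name!r}"
            )
        if len(buffer) >= max_buffer_size:
            raise MemoryError(
                f"mate-pairing buffer exceeded {max_buffer_size} outstanding "
                "records; is the input a valid paired-end file?"
            )
        buffer[own_key] = a
        peak = max(peak, len(buffer))
    if buffer:
        logger.warning(
            "%d paired record(s) had no matching mate", len(buffer)
        )
    for a in buffer.values():
        yield (a, None) if a.pe_which == "first" else (None, a)
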