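"""Iterator-style parsers and writers for common HTS text formats.

FASTA, FASTQ, GFF2/GTF, GFF3, BED, bedGraph, Wiggle and VCF readers all
yield record objects converted to the internal zero-based half-open
coordinate convention; writers convert back to each format's native
convention (GFF 1-based closed, BED/bedGraph 0-based half-open, Wiggle
1-based). All readers are lazy: consuming k records reads O(k) lines.

Text SAM lives in :mod:`xseq.alignments` (the record class does real
coordinate work there); :func:`read_sam` re-exports it for symmetry.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from typing import Any, Iterator, TextIO

from .arrays import GenomicArray
from .core import GenomicInterval, SequenceWithQualities, normalize_strand

_FASTQ_OFFSETS = {"phred33": 33, "phred64": 64}


def _as_stream(source) -> TextIO:
    """Accept an open text stream or a path (with gzip convenience)."""
    if hasattr(source, "read"):
        return source
    source = str(source)
    if source.endswith(".gz"):
        return _io.TextIOWrapper(gzip.open(source, "rb"))
    return open(source, "rt")


class ParseError(ValueError):
    """A malformed input line; carries the line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(source) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) tuples; name is the header up to whitespace."""
    stream = _as_stream(source)
    name = None
    chunks: list[str] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if line.startswith(">"):
            if name is not None:
                yield name, "".join(chunks)
            name = line[1:].split()[0] if line[1:].split() else ""
            chunks = []
        elif line.strip():
            if name is None:
                raise ParseError("sequence data before any '>' header", lineno)
            chunks.append(line.strip())
    if name is not None:
        yield name, "".join(chunks)


def write_fasta(records, sink: TextIO, width: int = 70) -> None:
    for name, seq in records:
        sink.write(f">{name}\n")
        for i in range(0, len(seq), width):
            sink.write(seq[i : i + width] + "\n")


def read_fastq(
    source, qual_scale: str = "phred33"
) -> Iterator[SequenceWithQualities]:
    """Yield reads from 4-line FASTQ records, decoding qualities.

    ``qual_scale`` selects the ASCII offset: "phred33" (Sanger/Illumina 1.8+,
    the default) or "phred64" (legacy Illumina).
    """
    if qual_scale not in _FASTQ_OFFSETS:
        raise ValueError(f"unknown quality scale {qual_scale!r}")
    offset = _FASTQ_OFFSETS[qual_scale]
    stream = _as_stream(source)
    lineno = 0
    while True:
        head = stream.readline()
        if not head:
            return
        lineno += 1
        head = head.rstrip("\n")
        if not head:
            continue
        if not head.startswith("@"):
            raise ParseError(f"expected '@' header, got {head[:30]!r}", lineno)
        seq = stream.readline().rstrip("\n")
        plus = stream.readline().rstrip("\n")
        qual_line = stream.readline().rstrip("\n")
        if not qual_line and not seq:
            raise ParseError("truncated FASTQ record", lineno)
        lineno += 3
        if not plus.startswith("+"):
            raise ParseError(f"expected '+' separator, got {plus[:30]!r}", lineno - 1)
        if len(seq) != len(qual_line):
            raise ParseError(
                f"sequence length {len(seq)} != quality length {len(qual_line)}",
                lineno,
            )
        qual = [ord(c) - offset for c in qual_line]
        if any(q < 0 for q in qual):
            raise ParseError(
                f"negative quality score under scale {qual_scale}", lineno
            )
        yield SequenceWithQualities(head[1:], seq, qual)


def write_fastq(records, sink: TextIO, qual_scale: str = "phred33") -> None:
    offset = _FASTQ_OFFSETS[qual_scale]
    for rec in records:
        qual_line = "".join(chr(q + offset) for q in rec.qual)
        sink.write(f"@{rec.name}\n{rec.seq}\n+\n{qual_line}\n")


# ---------------------------------------------------------------------------
# GFF / GTF


@dataclass
class GenomicFeature:
    """One annotation record (an exon, gene, CDS, BED line, ...)."""

    name: str
    type: str
    iv: GenomicInterval
    source: str = "."
    score: float | None = None
    frame: int | None = None
    attr: dict[str, Any] = field(default_factory=dict)


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
            value = value.strip()
            if value.startswith('"') and value.endswith('"') and len(value) >= 2:
                value = value[1:-1]
        else:
            key, value = chunk, ""
        attrs[key.strip()] = value
    return attrs


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _sniff_gff_dialect(attr_text: str) -> str:
    first = attr_text.split(";", 1)[0].strip()
    if "=" in first and '"' not in first:
        return "gff"
    return "gtf"


def read_gff(source, dialect: str = "auto") -> Iterator[GenomicFeature]:
    """Yield features from GFF2/GTF or GFF3, converting to 0-based half-open.

    GFF columns 4/5 are 1-based closed, so internal ``start = col4 - 1`` and
    ``end = col5``. ``dialect`` controls attribute parsing: "gtf"
    (``key "value";`` pairs), "gff" (``key=value``), or "auto" to sniff per
    line.
    """
    if dialect not in ("auto", "gtf", "gff"):
        raise ValueError(f"unknown GFF dialect {dialect!r}")
    stream = _as_stream(source)
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ParseError(
                f"expected >= 8 tab-separated columns, got {len(fields)}", lineno
            )
        chrom, src, ftype, start_s, end_s, score_s, strand_s, frame_s = fields[:8]
        attr_text = fields[8] if len(fields) > 8 else ""
        try:
            start = int(start_s) - 1
            end = int(end_s)
        except ValueError:
            raise ParseError(
                f"non-integer coordinates {start_s!r}/{end_s!r}", lineno
            ) from None
        if start > end:
            raise ParseError(
                f"start {start_s} > end {end_s} after conversion", lineno
            )
        if start < 0:
            raise ParseError(f"coordinate {start_s} below 1", lineno)
        use = dialect if dialect != "auto" else _sniff_gff_dialect(attr_text)
        attrs = (
            _parse_gff3_attributes(attr_text)
            if use == "gff"
            else _parse_gtf_attributes(attr_text)
        )
        strand = normalize_strand(strand_s if strand_s else ".")
        score = None if score_s in (".", "") else float(score_s)
        frame = None if frame_s in (".", "") else int(frame_s)
        name = (
            attrs.get("ID")
            or attrs.get("gene_id")
            or attrs.get("Name")
            or f"{ftype}:{chrom}:{start}-{end}"
        )
        yield GenomicFeature(
            name=name,
            type=ftype,
            iv=GenomicInterval(chrom, start, end, strand),
            source=src,
            score=score,
            frame=frame,
            attr=attrs,
        )


def write_gff(features, sink: TextIO, dialect: str = "gtf") -> None:
    """Write features back out, converting to GFF's 1-based closed columns."""
    for f in features:
        score = "." if f.score is None else format(f.score, "g")
        frame = "." if f.frame is None else str(f.frame)
        if dialect == "gtf":
            attr = " ".join(f'{k} "{v}";' for k, v in f.attr.items())
        else:
            attr = ";".join(f"{k}={v}" for k, v in f.attr.items())
        sink.write(
            "\t".join(
                [
                    f.iv.chrom,
                    f.source,
                    f.type,
                    str(f.iv.start + 1),
                    str(f.iv.end),
                    score,
                    f.iv.strand,
                    frame,
                    attr,
                ]
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# BED / bedGraph / Wiggle


def read_bed(source) -> Iterator[GenomicFeature]:
    """Yield BED3-6 lines; BED is already 0-based half-open (no shift)."""
    stream = _as_stream(source)
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if (
            not line.strip()
            or line.startswith("#")
            or line.startswith("track")
            or line.startswith("browser")
        ):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 3:
            raise ParseError(
                f"BED line needs >= 3 columns, got {len(fields)}", lineno
            )
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else "unnamed"
        score = (
            float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
        )
        strand = normalize_strand(fields[5]) if len(fields) > 5 else "."
        yield GenomicFeature(
            name=name,
            type="BED_line",
            iv=GenomicInterval(chrom, start, end, strand),
            score=score,
        )


def read_bedgraph(source) -> Iterator[tuple[GenomicInterval, float]]:
    stream = _as_stream(source)
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if (
            not line.strip()
            or line.startswith("#")
            or line.startswith("track")
            or line.startswith("browser")
        ):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(
                f"bedGraph line needs 4 columns, got {len(fields)}", lineno
            )
        yield GenomicInterval(fields[0], int(fields[1]), int(fields[2])), float(
            fields[3]
        )


def _fmt_value(v) -> str:
    return format(v, "g") if isinstance(v, float) else str(v)


def write_bedgraph(arr: GenomicArray, sink: TextIO) -> None:
    """Export a numeric array's non-default steps as bedGraph lines.

    Steps holding the array's default value are omitted; lines are emitted
    in coordinate order. Stranded arrays cannot be represented in bedGraph
    (it has no strand column) and are rejected.
    """
    if arr.typecode not in ("d", "i"):
        raise TypeError("bedGraph export requires a numeric array")
    if arr.stranded:
        raise ValueError(
            "bedGraph has no strand column; export each strand separately"
        )
    for iv, value in arr.steps():
        if value == arr.default:
            continue
        sink.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_fmt_value(value)}\n")


def read_wiggle(source) -> Iterator[tuple[GenomicInterval, float]]:
    """Yield (interval, value) from fixedStep/variableStep Wiggle tracks.

    Wiggle positions are 1-based; the yielded intervals are 0-based
    half-open of width ``span`` (default 1).
    """
    stream = _as_stream(source)
    mode = None
    chrom = ""
    pos = 0
    step = 1
    span = 1
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("track"):
            continue
        if line.startswith("fixedStep") or line.startswith("variableStep"):
            params = dict(
                kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
            )
            chrom = params.get("chrom", "")
            span = int(params.get("span", 1))
            if line.startswith("fixedStep"):
                mode = "fixed"
                pos = int(params["start"]) - 1
                step = int(params.get("step", 1))
            else:
                mode = "variable"
            continue
        if mode is None:
            raise ParseError("data line before any step declaration", lineno)
        if mode == "fixed":
            yield GenomicInterval(chrom, pos, pos + span), float(line)
            pos += step
        else:
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(
                    "variableStep data line needs 'position value'", lineno
                )
            p = int(fields[0]) - 1
            yield GenomicInterval(chrom, p, p + span), float(fields[1])


def write_wiggle(arr: GenomicArray, sink: TextIO, track_name: str = "track") -> None:
    """Export non-default steps as variableStep span-1 Wiggle (1-based)."""
    if arr.typecode not in ("d", "i"):
        raise TypeError("Wiggle export requires a numeric array")
    by_chrom: dict[str, list[tuple[int, int, Any]]] = {}
    for iv, value in arr.steps():
        if value == arr.default:
            continue
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
    for chrom in sorted(by_chrom):
        sink.write(f"variableStep chrom={chrom}\n")
        for start, end, value in by_chrom[chrom]:
            for p in range(start, end):
                sink.write(f"{p + 1} {_fmt_value(value)}\n")


# ---------------------------------------------------------------------------
# VCF


@dataclass
class VcfRecord:
    """One VCF site; ``pos0`` is the POS column converted to 0-based."""

    chrom: str
    pos0: int
    id: str
    ref: str
    alt: list[str]
    qual: float | None
    filter: str
    info: dict[str, Any]
    genotypes: list[str] = field(default_factory=list)


def read_vcf(source) -> Iterator[VcfRecord]:
    """Yield VCF data lines; header ('#') lines are skipped.

    INFO is split on ';' then '='; bare keys become flags with value True.
    Per-sample parsing is minimal: only the GT subfield is extracted.
    """
    stream = _as_stream(source)
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ParseError(
                f"VCF data line needs >= 8 fields, got {len(fields)}", lineno
            )
        chrom, pos_s, vid, ref, alt_s, qual_s, filt, info_s = fields[:8]
        info: dict[str, Any] = {}
        for chunk in info_s.split(";"):
            if not chunk or chunk == ".":
                continue
            if "=" in chunk:
                k, _, v = chunk.partition("=")
                info[k] = v
            else:
                info[chunk] = True
        genotypes: list[str] = []
        if len(fields) > 9:
            fmt = fields[8].split(":")
            if "GT" in fmt:
                gi = fmt.index("GT")
                genotypes = [
                    s.split(":")[gi] if gi < len(s.split(":")) else "."
                    for s in fields[9:]
                ]
        yield VcfRecord(
            chrom=chrom,
            pos0=int(pos_s) - 1,
            id=vid,
            ref=ref,
            alt=[] if alt_s == "." else alt_s.split(","),
            qual=None if qual_s == "." else float(qual_s),
            filter=filt,
            info=info,
            genotypes=genotypes,
        )


def read_sam(source):
    """Yield SamAlignment records from a text SAM stream (header skipped)."""
    from .alignments import read_sam as _read_sam

    return _read_sam(source)
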