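"""Core value types: genomic coordinates and reads with base-call qualities.

Every coordinate in this package is zero-based; intervals are half-open
``[start, end)``. Parsers convert from each file format's native convention
on the way in, and writers convert back on the way out, so code built on
these types never sees a one-based or closed coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def flip_strand(strand: str) -> str:
    """Return the opposite strand; "." is its own opposite."""
    if strand == "+":
        return "-"
    if strand == "-":
        return "+"
    if strand == ".":
        return "."
    raise ValueError(f"invalid strand symbol {strand!r}")


def normalize_strand(strand: str) -> str:
    """Map a file-format strand symbol onto the internal {+, -, .} alphabet.

    GFF's "?" (strand relevant but unknown) is normalized to "." with a
    logged warning; anything else unknown is an error.
    """
    if strand in STRANDS:
        return strand
    if strand == "?":
        logger.warning('strand "?" normalized to "."')
        return "."
    raise ValueError(f"invalid strand symbol {strand!r}")


@dataclass(frozen=True, order=False)
class GenomicPosition:
    """A single zero-based position on a named chromosome."""

    chrom: str
    pos: int
    strand: str = "."

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"position must be non-negative, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand symbol {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}/{self.strand}"


@dataclass(frozen=True)
class GenomicInterval:
    """Zero-based half-open coordinate range ``[start, end)`` with a strand.

    Equality includes the strand; :meth:`overlaps` deliberately does not —
    whether strand matters for an overlap is a policy decision that belongs
    to the caller (e.g. the stranded/unstranded counting modes).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be non-negative, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end {self.end} precedes start {self.start}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start_d(self) -> int:
        """The 5'-most position in reading direction."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def end_d(self) -> int:
        """One past the 3'-most position in reading direction.

        For "-" intervals this is ``start - 1`` (walking leftwards).
        """
        return self.end if self.strand != "-" else self.start - 1

    @property
    def start_as_pos(self) -> GenomicPosition:
        return GenomicPosition(self.chrom, self.start, self.strand)

    @property
    def start_d_as_pos(self) -> GenomicPosition:
        return GenomicPosition(self.chrom, self.start_d, self.strand)

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two ranges share at least one position.

        Strand is not consulted. Under the half-open convention a
        zero-length interval overlaps nothing, including itself.
        """
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff ``other`` lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __lt__(self, other: "GenomicInterval"):
        return (self.chrom, self.start, self.end, self.strand) < (
            other.chrom,
            other.start,
            other.end,
            other.strand,
        )

    def __str__(self) -> str:
        return f"{self.chrom}:[{self.start},{self.end})/{self.strand}"


@dataclass
class SequenceWithQualities:
    """A named nucleotide sequence with per-base Phred quality scores."""

    name: str
    seq: str
    qual: list[int] = field(default_factory=list)

    def __post_init__(self):
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.name!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )
        if any(q < 0 for q in self.qual):
            raise ValueError(f"read {self.name!r}: negative quality score")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceWithQualities":
        """Reverse-complement the sequence and reverse the qualities.

        N maps to N. Applying the operation twice returns an equal record.
        """
        bad = set(self.seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(
                f"cannot reverse-complement: unknown nucleotide "
                f"{sorted(bad)[0]!r} in read {self.name!r}"
            )
        return SequenceWithQualities(
            name=self.name,
            seq=self.seq.translate(_COMPLEMENT)[::-1],
            qual=self.qual[::-1],
        )


def reverse_complement(x):
    """Reverse-complement a raw string or a :class:`SequenceWithQualities`."""
    if isinstance(x, SequenceWithQualities):
        return x.reverse_complement()
    bad = set(x.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"unknown nucleotide {sorted(bad)[0]!r}")
    return x.translate(_COMPLEMENT)[::-1]
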