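"""Per-cycle nucleotide composition and base-call quality tabulation.

The initial quality check for a sequencing run: for every position (cycle)
in the reads, count how often each nucleotide occurs and how often each
quality score occurs. Aligned minus-strand SAM records are
reverse-complemented first so positions always refer to sequencing cycles,
and SAM input can be split into aligned/unaligned summaries.
"""

from __future__ import annotations

from typing import Iterable, TextIO

import numpy as np

from .alignments import SamAlignment
from .core import SequenceWithQualities

BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class QaSummary:
    """Position-by-base and position-by-quality count matrices.

    For every position p below ``max_len``, the base counts at p sum to
    the number of reads of length > p, and likewise for the quality
    counts. Summaries are additive: tabulating two inputs separately and
    adding the summaries equals tabulating their concatenation.
    """

    def __init__(self):
        self.max_len = 0
        self.base_counts = np.zeros((0, len(BASES)), dtype=np.int64)
        self.qual_counts = np.zeros((0, 0), dtype=np.int64)
        self.n_reads = 0
        self.n_aligned = 0

    def _grow(self, length: int, max_qual: int) -> None:
        if length > self.base_counts.shape[0]:
            pad = length - self.base_counts.shape[0]
            self.base_counts = np.vstack(
                [self.base_counts, np.zeros((pad, len(BASES)), dtype=np.int64)]
            )
            self.qual_counts = np.vstack(
                [
                    self.qual_counts,
                    np.zeros((pad, self.qual_counts.shape[1]), dtype=np.int64),
                ]
            )
        if max_qual + 1 > self.qual_counts.shape[1]:
            pad = max_qual + 1 - self.qual_counts.shape[1]
            self.qual_counts = np.hstack(
                [
                    self.qual_counts,
                    np.zeros((self.qual_counts.shape[0], pad), dtype=np.int64),
                ]
            )

    def add_read(self, read: SequenceWithQualities) -> None:
        n = len(read.seq)
        self.n_reads += 1
        if n == 0:
            return
        self._grow(n, max(read.qual) if read.qual else 0)
        self.max_len = max(self.max_len, n)
        for p, base in enumerate(read.seq.upper()):
            self.base_counts[p, _BASE_INDEX.get(base, _BASE_INDEX["N"])] += 1
        for p, q in enumerate(read.qual):
            self.qual_counts[p, q] += 1

    def __add__(self, other: "QaSummary") -> "QaSummary":
        out = QaSummary()
        rows = max(self.base_counts.shape[0], other.base_counts.shape[0])
        cols = max(self.qual_counts.shape[1], other.qual_counts.shape[1])
        out._grow(rows, cols - 1 if cols else 0)
        for src in (self, other):
            r, c = src.base_counts.shape[0], src.qual_counts.shape[1]
            out.base_counts[:r] += src.base_counts
            out.qual_counts[:r, :c] += src.qual_counts
        out.max_len = max(self.max_len, other.max_len)
        out.n_reads = self.n_reads + other.n_reads
        out.n_aligned = self.n_aligned + other.n_aligned
        return out

    def write_base_tsv(self, sink: TextIO) -> None:
        sink.write("position\t" + "\t".join(BASES) + "\n")
        for p in range(self.max_len):
            sink.write(
                f"{p}\t" + "\t".join(str(c) for c in self.base_counts[p]) + "\n"
            )

    def write_qual_tsv(self, sink: TextIO) -> None:
        n_quals = self.qual_counts.shape[1]
        sink.write(
            "position\t" + "\t".join(str(q) for q in range(n_quals)) + "\n"
        )
        for p in range(self.max_len):
            sink.write(
                f"{p}\t" + "\t".join(str(c) for c in self.qual_counts[p]) + "\n"
            )


def _cycle_space_read(a: SamAlignment) -> SequenceWithQualities:
    # aligned minus-strand records store the reference-strand sequence;
    # undo that so positions mean sequencing cycles
    if a.aligned and a.iv is not None and a.iv.strand == "-":
        return a.read.reverse_complement()
    return a.read


def tabulate(
    reads: Iterable[SequenceWithQualities | SamAlignment],
    split_aligned: bool = False,
):
    """Tabulate reads into a :class:`QaSummary`.

    With ``split_aligned`` (SAM input), returns an (aligned, unaligned)
    pair of summaries instead of one combined summary.
    """
    if split_aligned:
        aligned_summary, unaligned_summary = QaSummary(), QaSummary()
        for item in reads:
            if not isinstance(item, SamAlignment):
                raise TypeError(
                    "split_aligned requires SAM alignment records"
                )
            if item.aligned:
                aligned_summary.add_read(_cycle_space_read(item))
                aligned_summary.n_aligned += 1
            else:
                unaligned_summary.add_read(item.read)
        return aligned_summary, unaligned_summary
    summary = QaSummary()
    for item in reads:
        if isinstance(item, SamAlignment):
            summary.add_read(_cycle_space_read(item))
            if item.aligned:
                summary.n_aligned += 1
        else:
            summary.add_read(item)
    return summary
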