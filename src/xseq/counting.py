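"""Gene-level read and fragment counting for differential expression.

Given alignments and a gene model (GTF/GFF), count for each gene how many
reads — or fragments, for paired-end data — overlap its exons. Because the
counts feed differential-expression tests, only units assignable to exactly
one gene are counted: multi-mapped reads and reads overlapping several
genes would otherwise let one gene's signal bleed into another's, so they
are routed to dedicated outcome categories instead.

Every counting unit ends in exactly one bucket, so gene counts plus the
five special categories always sum to the number of units processed.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from functools import reduce
from typing import Iterable, Iterator, TextIO

from .alignments import (
    SamAlignment,
    pair_alignments_with_buffer,
    read_sam,
)
from .arrays import GenomicArrayOfSets
from .core import GenomicInterval, flip_strand
from .io import GenomicFeature, read_gff

logger = logging.getLogger(__name__)

MODES = ("union", "intersection-strict", "intersection-nonempty")
STRANDED_CHOICES = ("yes", "no", "reverse")

SPECIALS = (
    "no_feature",
    "ambiguous",
    "too_low_aQual",
    "not_aligned",
    "alignment_not_unique",
)


@dataclass(frozen=True)
class CountOptions:
    """Options controlling the counting run.

    ``stranded="yes"`` requires a read (mate 1) to match the gene's strand
    and mate 2 to oppose it; ``"reverse"`` is the converse (dUTP-style
    protocols); ``"no"`` ignores strand. ``min_aqual`` routes units whose
    aligned mate falls below the MAPQ threshold to too_low_aQual.
    """

    mode: str = "union"
    stranded: str = "yes"
    min_aqual: int = 10
    feature_type: str = "exon"
    id_attribute: str = "gene_id"
    paired: bool = False
    skip_flagged: bool = False  # drop QC-fail / duplicate records entirely
    log_every: int = 100_000

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.stranded not in STRANDED_CHOICES:
            raise ValueError(
                f"unknown strandedness {self.stranded!r}; "
                f"choose from {STRANDED_CHOICES}"
            )
        if self.min_aqual < 0:
            raise ValueError("min_aqual must be non-negative")


@dataclass
class CountTable:
    """Per-gene counts plus the special outcome categories."""

    counts: dict[str, int] = field(default_factory=dict)
    specials: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in SPECIALS}
    )

    @property
    def total_units(self) -> int:
        return sum(self.counts.values()) + sum(self.specials.values())

    def write(self, sink: TextIO) -> None:
        """Two-column TSV: gene rows first, then '__'-prefixed specials."""
        for gene, n in self.counts.items():
            sink.write(f"{gene}\t{n}\n")
        for key in SPECIALS:
            sink.write(f"__{key}\t{self.specials[key]}\n")

    def as_dict(self) -> dict[str, int]:
        out = dict(self.counts)
        out.update({f"__{k}": v for k, v in self.specials.items()})
        return out


def build_feature_index(
    features: Iterable[GenomicFeature],
    opts: CountOptions = CountOptions(),
) -> tuple[GenomicArrayOfSets, list[str]]:
    """Index features of the configured type under their gene identifier.

    Returns the set-valued array plus gene ids in first-appearance order
    (genes no read ever hits still appear in the output with count 0).
    When counting is stranded, features are stored on their own strand and
    a strandless feature is an error — strand-aware counting cannot place
    it.
    """
    stranded = opts.stranded != "no"
    index = GenomicArrayOfSets("auto", stranded=stranded)
    gene_ids: dict[str, None] = {}
    n = 0
    for feat in features:
        if feat.type != opts.feature_type:
            continue
        gene_id = feat.attr.get(opts.id_attribute)
        if gene_id is None:
            raise ValueError(
                f"feature of type {feat.type!r} at {feat.iv} lacks the "
                f"{opts.id_attribute!r} attribute"
            )
        iv = feat.iv
        if stranded:
            if iv.strand == ".":
                raise ValueError(
                    f"feature {gene_id!r} at {iv} has no strand but counting "
                    'is stranded; use stranded="no"'
                )
        else:
            iv = replace(iv, strand=".")
        index.add_feature(iv, gene_id)
        gene_ids.setdefault(gene_id)
        n += 1
    logger.info("indexed %d %s features, %d genes", n, opts.feature_type, len(gene_ids))
    return index, list(gene_ids)


def _is_multimapped(mates: list[SamAlignment]) -> bool:
    for m in mates:
        nh = m.optional_field("NH")
        if nh is not None and nh > 1:
            return True
        if m.not_primary_alignment:
            return True
    return False


def _effective_strand(mate: SamAlignment, opts: CountOptions) -> str:
    """The strand a feature must lie on for this mate to hit it."""
    if opts.stranded == "no":
        return "."
    assert mate.iv is not None
    first = mate.pe_which in ("first", "not_paired")
    if opts.stranded == "yes":
        return mate.iv.strand if first else flip_strand(mate.iv.strand)
    return flip_strand(mate.iv.strand) if first else mate.iv.strand


def assign_unit(
    unit,
    index: GenomicArrayOfSets,
    opts: CountOptions = CountOptions(),
) -> str:
    """Assign one counting unit to a gene id or a special category.

    ``unit`` is a single :class:`SamAlignment` or a (first, second) mate
    tuple where either slot may be None. The decision cascade:

    1. no aligned mate → ``__not_aligned``
    2. multi-mapped (NH > 1 or secondary flag on any mate)
       → ``__alignment_not_unique``
    3. any aligned mate below the MAPQ threshold → ``__too_low_aQual``
    4. collect the annotation step sets under every covered reference
       interval of every aligned mate (strand-matched per the stranded
       option) and combine them per the mode; empty → ``__no_feature``,
       several genes → ``__ambiguous``, one gene → count it.

    A pair with exactly one aligned mate is assigned from that mate alone:
    it still evidences one cDNA fragment.
    """
    if isinstance(unit, SamAlignment):
        mates = [unit]
    else:
        mates = [m for m in unit if m is not None]
    aligned = [m for m in mates if m.aligned]
    if not aligned:
        return "__not_aligned"
    if _is_multimapped(aligned):
        return "__alignment_not_unique"
    if any(m.aQual < opts.min_aqual for m in aligned):
        return "__too_low_aQual"
    step_sets: list[frozenset] = []
    for mate in aligned:
        strand = _effective_strand(mate, opts)
        for block in mate.covered_ref_intervals():
            query = GenomicInterval(block.chrom, block.start, block.end, strand)
            try:
                steps = index.steps(query)
            except KeyError:
                # chromosome absent from the annotation: no features there
                steps = [(query, frozenset())]
            step_sets.extend(s for _, s in steps)
    if not step_sets:
        return "__no_feature"
    if opts.mode == "union":
        genes = frozenset().union(*step_sets)
    elif opts.mode == "intersection-strict":
        genes = reduce(frozenset.__and__, step_sets)
    else:  # intersection-nonempty
        nonempty = [s for s in step_sets if s]
        genes = reduce(frozenset.__and__, nonempty) if nonempty else frozenset()
    if not genes:
        return "__no_feature"
    if len(genes) == 1:
        return next(iter(genes))
    return "__ambiguous"


def count_units(
    units: Iterable,
    index: GenomicArrayOfSets,
    gene_ids: list[str],
    opts: CountOptions = CountOptions(),
) -> CountTable:
    """Assign every unit and tally the results into a count table."""
    table = CountTable(counts={g: 0 for g in gene_ids})
    n = 0
    for unit in units:
        outcome = assign_unit(unit, index, opts)
        if outcome.startswith("__"):
            table.specials[outcome[2:]] += 1
        else:
            # a gene discovered only through reads keeps table order stable
            table.counts[outcome] = table.counts.get(outcome, 0) + 1
        n += 1
        if opts.log_every and n % opts.log_every == 0:
            print(f"{n} counting units processed", file=sys.stderr)
    return table


def _units_from_alignments(
    alignments: Iterable[SamAlignment], opts: CountOptions
) -> Iterator:
    for a in alignments:
        if opts.skip_flagged and (a.failed_platform_qc or a.pcr_or_optical_duplicate):
            continue
        yield a


def count_alignments(
    alignments: Iterable[SamAlignment],
    features: Iterable[GenomicFeature],
    opts: CountOptions = CountOptions(),
) -> CountTable:
    """Count already-parsed alignments against already-parsed features."""
    index, gene_ids = build_feature_index(features, opts)
    stream = _units_from_alignments(alignments, opts)
    units = pair_alignments_with_buffer(stream) if opts.paired else stream
    return count_units(units, index, gene_ids, opts)


def count_file(
    sam_source,
    gff_source,
    opts: CountOptions = CountOptions(),
) -> CountTable:
    """Count a SAM file against a GTF/GFF gene model; the htseq-count task.

    Paired mode joins records through the mate-pairing buffer, so both
    name-sorted and position-sorted input work; each joined pair is one
    counting unit (a fragment), per the principle that two mates evidence
    a single cDNA fragment.
    """
    return count_alignments(read_sam(sam_source), read_gff(gff_source), opts)
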