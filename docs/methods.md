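# Methods

This note records the models, conventions and design choices behind xseq,
in the spirit of the methods documentation of mature scientific Python
packages: what the code computes, under which assumptions, and what its
tests do and do not demonstrate.

## Coordinate model

All coordinates are zero-based; intervals are half-open `[start, end)`.
Strand is one of `+`, `-`, `.` (unstranded); GFF's `?` (unknown but
relevant) is normalized to `.` with a logged warning, since the counting
policies only distinguish known-strand from strand-free. Interval
*equality* includes strand, interval *overlap* does not: whether strand
matters for an overlap is a policy question (stranded vs unstranded
counting), which callers decide explicitly. Under the half-open
convention a zero-length interval overlaps nothing, including itself.
Ordering of intervals is lexicographic on (chrom, start, end, strand) —
the strand tiebreak is our choice; nothing downstream depends on it.
Chromosome names are opaque strings: no `chr`-prefix normalization is
attempted, because silent renaming produces silently wrong results —
a naming mismatch surfaces as zero overlap plus a "unknown chromosome"
diagnostic instead.

## Step storage

A `GenomicArray` lane is stored as parallel sorted lists of breakpoints
and values; step *i* runs from `starts[i]` to `starts[i+1]` (the last
step to the lane end, which may be conceptually infinite for auto-created
lanes). Invariants maintained by every mutation: breakpoints strictly
increasing starting at 0, and adjacent values never comparing equal
(steps are maximal). Point lookup is a binary search (O(log n) in steps
per lane, the complexity contract); interval assignment rebuilds the two
lists around the affected range (O(n) worst case per write), which is the
right trade-off at annotation scale — tens of thousands of steps per
chromosome — and keeps the coalescing logic in one place.

The dense backend stores a numpy buffer per lane and answers
`steps()` queries by locating value changes with `np.diff`; it requires
declared chromosome lengths and numeric values (object values make no
sense densely). The two backends are required to answer identically and
are tested against each other and against a brute-force per-base
dictionary oracle.

`GenomicArrayOfSets` stores `frozenset` values. Immutability is what
makes step splitting safe: a split copies the *reference* to the set, and
insertion replaces a step's set with a new union rather than mutating in
place, so no aliasing between steps can occur. Consequences that the
property tests exercise: insertion is idempotent, never removes
previously inserted features, and the final step structure is independent
of insertion order.

Queries beyond a declared lane end fail loudly rather than clip. Clipping
would be convenient for window operations but hides real coordinate bugs
(e.g. reads aligned past the end of a mis-declared contig); the one place
clipping is genuinely wanted — anchored profile windows — handles it
explicitly with a per-position divisor.

## Anchored aggregate profiles

`aggregate_profile(cov, anchors, halfwidth)` returns a vector of length
`2*halfwidth` whose element `j` is the mean coverage at signed offset
`j - halfwidth` from the anchors *in reading direction*: a minus-strand
anchor's window is reversed so that index 0 is always 5'-most. Windows
truncated by lane boundaries contribute only their defined positions; the
divisor is tracked per offset, and offsets covered by no anchor are
reported as 0 (not NaN) since downstream plotting treats them as absent
signal.

## SAM and CIGAR

CIGAR parsing follows the SAM consumption table: M/=/X consume query and
reference, I/S query only, D/N reference only, H/P neither. The parser
walks the string once with two cursors and stores per-operation query
ranges and reference intervals, validating that query-consuming sizes sum
to the sequence length when it is known. Hard-clipped bases are recorded
as operations with empty query ranges; the clipped sequence is not
reconstructed.

The counting footprint of an alignment (`covered_ref_intervals`) is the
set of maximal reference runs covered by M/=/X/D, split at N gaps. D is
included because small deletions are alignment noise within an exon; N is
excluded because an intron skip must not make a read overlap a gene lying
between its exons. This is the standard spliced RNA-seq semantics.

Multi-mapping detection uses the NH optional tag when present (NH > 1)
and otherwise the secondary-alignment flag (0x100) — aligners disagree on
which they emit, so both are honoured.

Mate pairing buffers records keyed by (QNAME, first/second role, own
position, mate position); a record joins the buffered record whose key
mirrors its own. The position pair is what keeps multiple alignments of
the same read pair from cross-joining. Unmatched records are yielded as
orphans at end of input with their count logged; a third record carrying
an already-buffered key is an input error. The buffer is capped
(configurable, default 3 million records) so pathological input fails
with a message instead of exhausting memory.

SAM serialization is a semantic inverse of parsing: re-parsing a written
line reproduces all 11 mandatory fields and the typed optional fields.
The writer normalizes RNEXT to `=` when the mate shares the chromosome
and emits `*` for unaligned placeholders, so byte identity with
arbitrary third-party output is not guaranteed (and not needed).

## Counting semantics

Each counting unit (a read, or a mate pair = one fragment) is routed
through a fixed cascade: unaligned → `not_aligned`; multi-mapped →
`alignment_not_unique`; any aligned mate below the MAPQ threshold →
`too_low_aQual`; otherwise the unit's gene set is computed and resolves
to `no_feature` (empty), a gene (singleton) or `ambiguous` (larger). The
cascade order matters and is tested: a multi-mapped low-MAPQ read is
`alignment_not_unique`, not `too_low_aQual`.

The gene set is combined from the *per-step* sets of the annotation index
under every covered reference interval of every aligned mate — step
granularity, not one union per interval, which is what makes
`intersection-strict` send a half-in/half-out read to `no_feature`.
`union` takes the union of all step sets; `intersection-strict`
intersects all of them including empty ones; `intersection-nonempty`
intersects only the non-empty ones. An implied mode ordering follows and
is property-tested: a gene assigned by strict is assigned by nonempty,
and union assigns the same gene or `ambiguous`, never a different gene.

Strandedness: with `yes`, mate 1 must match the feature strand and
mate 2 oppose it; `reverse` is the converse (dUTP protocols); `no`
ignores strand (features are indexed strandless). A strandless feature
under stranded counting is an error rather than a guess.

A pair with exactly one aligned mate is assigned from that mate alone —
it still evidences one fragment. Each additional reported alignment of a
multi-mapped read (or pair) is its own counting unit routed to
`alignment_not_unique`; this keeps the conservation identity (gene counts
plus special categories = units processed) exact and record-countable.
QC-fail and duplicate flags are ignored by default with an explicit
`skip_flagged` opt-out, the least-surprise default.

Defaults: mode `union`, stranded `yes`, MAPQ threshold 10, feature type
`exon`, id attribute `gene_id` — the conventional defaults for this task.

## The synthetic-data generator

`xseq.fixtures.generate` emulates the geometry that matters for counting
and nothing else. Default study conditions: 2 chromosomes × 100 kb,
50 genes of 3 × 300 bp exons with 200 bp introns, 20% of genes placed
overlapping their neighbour's last exon on the same strand (designed
ambiguity), 20 000 paired 75 bp fragments sampled uniformly from spliced
transcript coordinates (so mates cross exon junctions and get M/N
CIGARs), 0.5% per-base substitution errors, and 5% each of multi-mapped
fragments (NH:i:2 with a duplicated secondary alignment in a reserved
gene-free zone), unaligned fragments, and intergenic no-feature probes
placed in the same reserved zone. Reads are generated sense-stranded
(mate 1 on the gene strand), so a `reverse` counting run correctly sends
every regular fragment to `no_feature` — a useful polarity check.
Fragment lengths are uniform on [2·read_len, 2·read_len + 150] capped by
transcript length; base qualities uniform on Q30–Q40. All randomness
comes from one seeded `random.Random`; identical seeds give byte-identical
outputs.

What it does **not** emulate: realistic expression levels, quality decay
along cycles, indels, adapter read-through, or chimeric alignments.
Passing tests therefore demonstrate correctness of the *assignment
logic* under controlled geometry, not robustness to every artefact of
real libraries.

The recorded truth is computed by a brute-force geometric oracle inside
the generator: per covered block, the distinct per-base gene sets are
derived directly from the exon coordinate list (splitting at exon
boundaries), then combined with the same published mode/strand rules.
This path shares no code with the step containers, the CIGAR parser or
the counter — the generator knows its blocks before a CIGAR string is
ever built — so exact agreement between `count_file` and the truth is a
genuine two-route check.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale, chosen as
the sizes a scientist would use for a sanity run: 100 kb lanes with 200
insertions and 1 000 queries for the container oracle, 10 000 random
CIGARs, 5 000 shuffled mate pairs, and the 50-gene / 20 000-fragment
counting conditions above (the full suite completes in well under a
minute). All comparisons in the tests are exact — the quantities involved
(counts, sets, integer coordinates) admit no rounding — except the
aggregate profile, which is float arithmetic on exact integers and is
still compared exactly against its closed form.

## Known limitations

- Text SAM only; BAM/CRAM, BigWig and tabix-indexed access are out of
  scope (pysam appears solely as a test oracle).
- bedGraph export refuses stranded arrays (the format has no strand
  column); export each strand separately.
- VCF support covers the site columns and minimal GT extraction, not the
  full genotype-field semantics.
- The counter offers no fractional/multi-overlap counting or
  normalization; those belong to downstream differential-expression
  tools.
- Step-lane writes are O(n) per operation; bulk loading of very large
  annotations (millions of features per chromosome) would benefit from a
  batched build path that does not exist yet.
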