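# xseq

A Python framework for scripting high-throughput sequencing (HTS)
analyses: parsers for the common text formats, coordinate-safe record
classes, interval-keyed containers for position-associated genome data,
and two shell tools built on top of them — `xcount`, a gene-level
read/fragment counter that prepares RNA-Seq count tables for
differential-expression analysis, and `xqa`, a per-cycle read-quality
tabulator. A deterministic synthetic-data generator (`xfixture`) produces
genome + annotation + alignments with recorded counting ground truth, so
everything is testable offline.

It is written for bioinformaticians who need custom processing between the
standard pipeline tools: iterate over reads or alignments in a `for` loop,
look things up by genomic coordinate, and branch on the special cases
yourself.

## The core ideas

**One coordinate convention.** Every record uses zero-based, half-open
intervals `[start, end)`. Parsers convert on input (GTF's 1-based closed
columns, VCF POS, Wiggle positions), writers convert back on output, so
off-by-one bugs cannot cross module boundaries.

**Steps, not base pairs.** Position-associated data (coverage, scores,
annotation) is piecewise constant, so `GenomicArray` stores maximal runs
of constant value ("steps") keyed by sorted breakpoints — point lookup is
O(log n) in the number of steps. A numpy-backed dense mode is available
for genuinely per-base data; both backends answer queries identically.
`GenomicArrayOfSets` makes the step values *sets* of feature references:
inserting overlapping exons splits steps and duplicates sets, and the
union of step sets under a query interval is exactly the set of features
it overlaps — the natural annotation index for read counting.

**Coordinate-resolved CIGARs.** `SamAlignment.cigar` is a list of
`CigarOperation`s, each carrying its half-open range in the read and its
`GenomicInterval` on the reference, computed by a single cursor walk
(M/=/X consume both, I/S query only, D/N reference only, H/P neither).
Gapped and clipped alignments then need no special-casing: the counting
footprint is simply the M/=/X/D runs, split at N (intron) gaps.

**Count fragments, assign uniquely.** For differential expression,
`xcount` counts each read — or each *fragment*, for paired-end data,
since two mates evidence one cDNA molecule — toward exactly one gene.
Multi-mapped reads (NH tag > 1 or secondary flag), reads overlapping
several genes, sub-threshold MAPQ and unaligned reads go to dedicated
categories (`__alignment_not_unique`, `__ambiguous`, `__too_low_aQual`,
`__not_aligned`, `__no_feature`), so gene counts plus categories always
sum to the number of units processed. Three overlap-resolution modes
(`union`, `intersection-strict`, `intersection-nonempty`) and three
strandedness settings (`yes`, `no`, `reverse`) are supported. Paired-end
records are joined by a buffered mate-pairing iterator keyed on read name
plus mutual (position, mate-position), so name- and position-sorted input
both work.

## Worked example

```python
import io
from xseq import CountOptions, count_file
from xseq.fixtures import FixtureSpec, generate

fx = generate(FixtureSpec(seed=7, n_genes=8, n_fragments=500))
opts = CountOptions(mode="union", stranded="yes", paired=True)
table = count_file(io.StringIO(fx.sam), io.StringIO(fx.gtf), opts)
table.write(__import__("sys").stdout)
```

prints (`examples/03_count_fragments.py` shows the truth columns too):

```
G0001	49
G0002	55
G0003	46
G0004	52
G0005	66
G0006	49
G0007	39
G0008	44
__no_feature	28
__ambiguous	21
__too_low_aQual	0
__not_aligned	30
__alignment_not_unique	42
```

Each gene row is the number of fragments assigned uniquely to that gene's
exons; the `__` rows are the discarded categories. The 521 units (500
designed fragments plus one extra alignment per multi-mapped fragment)
are fully accounted for: rows sum to 521, and every row equals the
generator's recorded ground truth. The same run from the shell:

```sh
xfixture --seed 7 --spec small.json --out fx/
xcount --paired --mode union --stranded yes fx/reads.sam fx/genes.gtf
```

The other examples demonstrate the containers
(`examples/01_interval_containers.py`), anchored aggregate coverage
profiles such as TSS plots (`examples/02_tss_profile.py`) and per-cycle
quality tabulation (`examples/04_read_qa.py`).

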