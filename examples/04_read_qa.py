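"""Per-cycle read quality assessment from a SAM file.

Tabulates nucleotide composition and base-call quality per sequencing
cycle, split into aligned and unaligned reads.
"""

import io

from xseq import read_sam, tabulate
from xseq.fixtures import FixtureSpec, generate
from xseq.qa import BASES

fx = generate(FixtureSpec(seed=3, n_genes=8, n_fragments=400))
aligned, unaligned = tabulate(
    read_sam(io.StringIO(fx.sam)), split_aligned=True
)

print(f"reads: {aligned.n_reads} aligned, {unaligned.n_reads} unaligned")
print("\nfirst 5 cycles of the aligned reads (base counts):")
print("cycle\t" + "\t".join(BASES))
for p in range(5):
    print(f"{p}\t" + "\t".join(str(c) for c in aligned.base_counts[p]))
mean_q = (
    (aligned.qual_counts[0] * range(aligned.qual_counts.shape[1])).sum()
    / aligned.qual_counts[0].sum()
)
print(f"\nmean quality at cycle 0: {mean_q:.1f}")
# each cycle's base counts sum to the number of reads reaching that cycle
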