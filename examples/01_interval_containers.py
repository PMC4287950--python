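"""Piecewise-constant genome containers: coverage and overlapping annotation.

Builds read coverage in a GenomicArray and an exon index in a
GenomicArrayOfSets, then queries both by coordinate.
"""

from xseq import GenomicArray, GenomicArrayOfSets, GenomicInterval

# coverage: two 50 bp reads, one shifted by 25 bp
cov = GenomicArray({"chr1": 1000}, typecode="i")
cov.add_value(GenomicInterval("chr1", 100, 150), 1)
cov.add_value(GenomicInterval("chr1", 125, 175), 1)

print("coverage steps over [90, 185):")
for iv, value in cov.steps(GenomicInterval("chr1", 90, 185)):
    print(f"  {iv}  depth={value}")
# the overlap [125,150) has depth 2; flanks have depth 1; the rest 0

# annotation: two overlapping genes
genes = GenomicArrayOfSets({"chr1": 1000})
genes.add_feature(GenomicInterval("chr1", 100, 300), "geneA")
genes.add_feature(GenomicInterval("chr1", 250, 500), "geneB")

query = GenomicInterval("chr1", 280, 320)
print(f"\nfeatures overlapped by {query}: {sorted(genes.union(query))}")
# both genes: the query spans the geneA/geneB overlap and geneB alone
for iv, members in genes.steps(query):
    print(f"  {iv} -> {sorted(members)}")
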