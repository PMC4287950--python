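"""Aggregate coverage profile around transcription start sites.

Stacks coverage windows centred on a set of anchor positions and averages
them — the standard way to visualise, e.g., a histone mark's positioning
relative to TSSs.
"""

from xseq import (
    GenomicArray,
    GenomicInterval,
    GenomicPosition,
    aggregate_profile,
)

cov = GenomicArray({"chr1": 100_000}, typecode="i")
anchors = []
for i in range(20):
    tss = 2000 + i * 1000
    # a 60 bp block of signal starting right at each TSS
    cov.add_value(GenomicInterval("chr1", tss, tss + 60), 1)
    anchors.append(GenomicPosition("chr1", tss, "+"))

profile = aggregate_profile(cov, anchors, halfwidth=100)
print("mean coverage at offsets -100..+99 from the TSS:")
print("  upstream  (-100..-1):", profile[:100].sum() / 100)
print("  downstream (0..+59): ", profile[100:160].mean())
print("  downstream (+60..+99):", profile[160:].mean())
# signal sits exactly on [0, 60) downstream of the anchors: mean 1 there, 0
# elsewhere; minus-strand anchors would be mirrored automatically
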