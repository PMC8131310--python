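"""Partition a toy genome into six regional classes and apportion a peak.

The 10-kb genome carries one forward gene ([2000,5000), two exons, CDS
[2200,4500)), so every class percentage can be checked by hand. A peak
over [1500,2500) then splits 50/20/30 across promoter/5'UTR/coding exon.
"""

from epianno import (
    Annotation,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    TranscriptModel,
    build_region_partition,
    peak_region_distribution,
    region_fractions,
)

gene = GeneModel("g1", [
    TranscriptModel(
        "t1", "chr1", "+",
        [GenomicInterval("chr1", 2000, 2600, "+"),
         GenomicInterval("chr1", 4000, 5000, "+")],
        cds=GenomicInterval("chr1", 2200, 4500, "+"),
    )
])
annotation = Annotation([gene], {"chr1": 10_000})

partition = build_region_partition(annotation, promoter_bp=2000)
print("genome composition (% of 10 kb):")
for cls, pct in sorted(region_fractions(partition).items(), key=lambda kv: -kv[1]):
    print(f"  {cls:12s}: {pct:5.1f}")

peak = PeakSet([Peak(GenomicInterval("chr1", 1500, 2500), 1.0, 2000)], "leaf")
print("peak [1500,2500) mass by class (%):")
for cls, pct in peak_region_distribution(peak, partition).items():
    if pct > 0:
        print(f"  {cls:12s}: {pct:5.1f}")
# The peak covers 500 promoter bases, 200 5'UTR bases and 300 coding
# bases, hence 50/20/30.
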