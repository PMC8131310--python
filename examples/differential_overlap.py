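"""Fold-change DEGs, differential-peak genes and their Venn overlap.

Compares leaf vs root expression on a synthetic study with the
|log2 fold change| > 0.6 rule, maps synthetic differential H3K4me3
regions (here: the leaf peak set) to genes through the 2-kb-upstream
plus gene-body window, and counts the overlap of the two gene sets.
"""

from epianno.differential import (
    differential_expression,
    genes_with_differential_peaks,
    overlap_sets,
)
from epianno.synth import SynthConfig, simulate

fixture = simulate(SynthConfig(seed=11, n_known_genes=40, n_novel_transcripts=5,
                               n_samples=6, chrom_length=300_000))

# sample_00 is a leaf sample, sample_02 a root sample
res = differential_expression(fixture.expression, "sample_00", "sample_02",
                              log2fc_threshold=0.6, pseudocount=1.0)
degs = res.degs()
print(f"DEGs (|log2FC| > 0.6, leaf vs root): {len(degs)}")
print(f"  up in leaf: {len(res.genes_up_in('A'))}, up in root: {len(res.genes_up_in('B'))}")

diff_peak_genes = genes_with_differential_peaks(
    fixture.peaksets["leaf"], fixture.known, upstream_bp=2000
)
print(f"genes with a (leaf) peak in body + 2 kb upstream: {len(diff_peak_genes)}")

venn = overlap_sets(degs, diff_peak_genes, "DEG", "diff-peak")
print(
    f"overlap: {venn.intersection} shared, "
    f"{venn.only_a} DEG-only, {venn.only_b} peak-only"
)
# Peaks are planted only for expressed genes, so most DEGs that are
# expressed in leaf also carry a leaf peak.
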