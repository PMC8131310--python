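# Methods

## Coordinates and data model

All internal coordinates are 0-based half-open `[start, end)`; GTF's
1-based inclusive convention is converted only at the I/O boundary.
A transcript is an ordered chain of non-overlapping exons with an
optional single CDS interval; its "length" is the genomic span (first
exon start to last exon end), with summed exonic length available
separately. A gene is one or more transcripts on a chromosome; its span
is the union span and its TSS is the span start on the forward strand
and the span end on the reverse strand. Peak-to-gene association and
promoter definition operate on genes, not isoforms, because the
biological claim being tested — promoter-proximal H3K4me3 — concerns
transcription units.

Strand is `+`, `-` or `.` (unknown). Unknown is a first-class state:
assemblies of unstranded transcripts arrive without orientation, and
strand inference is a pipeline stage, never an I/O default.

## Discovery pipeline

**Merging.** Transcripts from all samples are clustered by
single-linkage over the relation *same chromosome ∧ exonic overlap ≥ 1
bp ∧ strands compatible* (unknown is compatible with anything). Each
connected component is fused into one transcript whose exons are the
coalesced union (0-bp adjacencies fuse) of member exons. When a
component contains both forward and reverse members joined through
unknown-strand bridges, it is split by strand before the union: known
forward and reverse members seed separate subclusters and each
unknown-strand member joins the side it shares more exonic overlap
with; a perfect tie leaves it in a strandless subcluster. Orientation is
never fabricated by a merge. There is no minimum overlap fraction: a
single shared base links transcripts, mirroring how locus-fusion
mergers behave, and the threshold choice matters little once assemblies
agree on exon boundaries.

**Novelty.** A merged transcript is a candidate iff its exonic overlap
with *every* reference transcript is zero. This is the strictest rule
that cannot relabel annotated exons as novel. Candidates wholly inside
one annotated intron are flagged `intronic` (intronic H3K4me3 mass is
real and such candidates are plausible nested transcripts); everything
else is `intergenic`.

**Co-occurrence.** Support in a tissue requires a peak that either
overlaps the candidate span by ≥ 1 bp or has its center strictly within
2000 bp (`max_center_dist`) of either span end. The union of the two
clauses matters: a broad peak covering the TSS of a short transcript
can fail the center-distance clause alone, and a peak just upstream of
the span fails the overlap clause alone. Tissues are scored
independently; the final novel set is every candidate supported in at
least one tissue.

**Strand rule.** Among peaks whose center is strictly within 2000 bp of
either span end, the smallest center-to-end distance decides: nearer
the left (smaller-coordinate) end ⇒ forward, nearer the right end ⇒
reverse. An exactly equidistant center, a tie between two peaks
implying opposite strands, or conflicting per-tissue calls all yield
unknown. The distance threshold is strict (`< 2000`), and the same
threshold gates both support and orientation.

## Region partition and peak metrics

Every base of the genome receives exactly one of six labels with
priority `coding_exon > utr5 > utr3 > intron > promoter > intergenic`.
UTRs are derived as exon-minus-CDS on the strand-appropriate side of
the CDS; transcripts without a CDS contribute their exons to the
coding-exon class rather than inventing UTRs. The promoter is the 2000
bp (`promoter_bp`) upstream of each gene TSS, clipped at chromosome
bounds, and claims only bases no genic class covers — a base inside one
gene's intron and another gene's promoter counts as genic, keeping the
intergenic fraction conservative. Unknown-strand genes (e.g. novels
whose orientation stayed unknown) get promoter windows on both sides.
The promoter width deliberately equals the peak-to-gene upstream window
so "promoter" in the partition and "upstream" in the association rule
mean the same thing.

The partition is materialised as one uint8 priority-code array per
chromosome, painted lowest-priority-first with an element-wise maximum;
the test suite checks it base-for-base against an independent
mask-and-select labeling on ~1000 random annotations, and that class bp
always sums exactly to genome length.

Peak distributions are bp-weighted: each peak's bases are tallied
against the classes covering them, so the class percentages are a true
partition of peak mass summing to 100 (not a one-class-per-peak vote).
Peaks beyond chromosome bounds are clipped with a warning.

Peak-to-gene association uses the gene body plus the strand-aware
2000-bp upstream window, requiring ≥ 1 bp of overlap; one peak may
associate with several genes. The identical rule maps externally
computed differential-H3K4me3 regions to genes.

## Coverage and profiling

Coverage tracks are stepwise (start, end, value) runs; uncovered bases
read as zero, and normalization to per-million-mapped-reads divides
every value by `mapped_reads / 1e6` exactly once (double normalization
raises). Meta-gene profiles use fixed-width flank bins (1000 bp in 50-bp
bins) and a gene body rescaled to 100 bins. Body bin means use
fractional-base weighting via the integral of the per-base step
function, so bodies shorter than the bin count remain well defined.
Reverse-strand genes are flipped so bin 0 is always 5′-most; flank
bases beyond the chromosome contribute zero signal.

Expression stratification ranks genes with FPKM > 0 ascending (ties
broken by gene id) and cuts them into nine equal-count groups; when the
count is not divisible the remainder goes to the lowest-expression
groups (20 genes ⇒ sizes 3,3,2,2,2,2,2,2,2). FPKM = 0 genes form a
separate not-expressed group. These rules make group membership fully
deterministic.

## Differential analysis and clustering

The differential-expression rule is a plain fold-change threshold:
log2FC = log2((FPKM_a + 1)/(FPKM_b + 1)), called differential when
|log2FC| > 0.6. The pseudocount of 1 keeps zero-FPKM transcripts
finite and is exposed as a parameter. Upstream significance testing of
the expression values is out of scope; so is two-condition peak
calling — differential H3K4me3 regions are inputs.

TSS-signal clustering max-normalizes each gene's signal vector (so
clusters capture shape, not amplitude), pre-assigns all-zero rows to a
dedicated cluster labeled −1, and runs k-means (k = 6 by default,
k-means++ initialization, ≤ 300 iterations) at a fixed seed. k-means is
a documented design choice where the clustering method was genuinely
open; determinism and recoverability of planted archetypes were the
selection criteria. Heatmap ordering of expression rows uses
average-linkage hierarchical clustering on log2(x+1) with Euclidean
distance, rows pre-sorted by id so the leaf order has a fixed tie rule.

## Synthetic studies

The generator lays features left-to-right along each chromosome with
intergenic gaps of 3–6 kb: known genes (1–5 exons of 150–600 bp,
introns 100–800 bp, CDS inset to create UTRs) interleaved with planted
novel transcripts (1–3 exons, no CDS), so planted novels never share an
exonic base with the reference by construction. Infeasible
configurations (features cannot fit) fail before any file is written.

The default study is ten RNA-seq samples assigned round-robin to three
tissues (leaf, stem, root). Each sample's assembly contains a fragment
of 80% of known genes (a random exon sub-chain with truncated outer
boundaries, emulating partial reassembly) plus each planted novel with
probability 0.7 (30% dropout), unstranded, with optional Gaussian
boundary jitter (off by default). Each novel is expressed in a random
non-empty subset of tissues; each tissue's peak set holds one
1000-bp peak per expressed transcript centered 500 bp upstream of its
TSS (strand-aware), plus optional decoy peaks placed deep in intergenic
gaps (off by default). FPKMs are drawn log-uniform over 2^0–2^8.
Coverage is a per-transcript kernel — a flat bump over the 500 bp
upstream of the TSS plus a linear 5′→3′ decay along the body — scaled by
FPKM and emitted as 50-bp bedGraph runs, so TSS signal grows with
expression and quantile-profile monotonicity is a testable property of
generator plus profiler. Everything derives from a single seed and
writes byte-identical files on re-run.

What the fixture does *not* emulate: read-level noise, alignment and
assembly artifacts, peak-caller boundary uncertainty, overlapping gene
architectures, and expression correlation structure across samples
within a tissue. Perfect precision/recall/strand accuracy on the
zero-decoy fixture therefore demonstrates correctness of the rules, not
expected performance on real libraries; the decoy, jitter and dropout
knobs exist to probe how the rules degrade.

Truth-based evaluation matches a prediction to a planted transcript
when their exonic overlap is ≥ 50% (`min_match_fraction`) of the
shorter one's exonic length. Precision is over predictions (reported as
1.0 with an explicit flag when there are no predictions), recall over
truth, and strand accuracy over matched pairs with a known true strand,
an unknown predicted strand counting as wrong.

## Problem sizes and determinism

The shipped verification runs use desk-scale genomes — up to 4
chromosomes of 0.9 Mb, 200 known genes, 300 planted novels, 10
samples — chosen so the full pipeline and its brute-force oracles
re-run in seconds while every rule still meets non-trivial cases
(multi-exon overlaps, reverse strands, promoter collisions). All
randomness flows through `numpy.random.default_rng(seed)`; pipeline
outputs are sorted by (chromosome, start, id) and are byte-identical
across reruns of the same configuration.

## Known limitations

- Novelty is all-or-nothing on exonic overlap: a real novel isoform
  sharing one exon with an annotated gene is discarded.
- The CDS is stored as a single interval per transcript; per-exon CDS
  phase is not tracked (the partition only needs the CDS extent).
- The strand rule cannot orient a transcript whose only peak sits
  mid-span, and deliberately refuses to guess.
- Multi-sample expression noise models, GFF3 multi-parent features and
  bigWig output are out of scope.
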