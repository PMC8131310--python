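import numpy as np
import pytest

from epianno.intervals import (
    Annotation,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)


def make_transcript(tid, chrom, exon_pairs, strand=".", cds=None):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs]
    cds_iv = GenomicInterval(chrom, *cds, strand) if cds else None
    return TranscriptModel(tid, chrom, strand, exons, cds=cds_iv)


def random_transcript(rng, tid, chrom="chr1", max_pos=10_000, strand=None):
    """A random valid transcript: 1-4 exons, non-overlapping, sorted."""
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, max_pos))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(20, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(1, 200))
    if strand is None:
        strand = rng.choice(["+", "-", "."])
    return make_transcript(tid, chrom, exons, strand=str(strand))


@pytest.fixture
def toy_annotation():
    """The 10-kb single-gene worked example used throughout the docs."""
    t = make_transcript(
        "t1", "chr1", [(2000, 2600), (4000, 5000)], strand="+", cds=(2200, 4500)
    )
    return Annotation([GeneModel("g1", [t])], {"chr1": 10_000})


def random_annotation(rng, n_genes=10, chrom_len=50_000, n_chroms=1):
    """A random multi-gene annotation; genes may overlap each other."""
    genes = []
    for g in range(n_genes):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        strand = str(rng.choice(["+", "-"]))
        t = random_transcript(
            rng, f"t{g}", chrom=chrom, max_pos=chrom_len - 3000, strand=strand
        )
        # clip to chromosome bounds
        if t.span.end > chrom_len:
            continue
        span = t.span
        cds = None
        if rng.random() < 0.7 and len(span) > 60:
            lo = span.start + int(rng.integers(1, max(2, len(span) // 3)))
            hi = span.end - int(rng.integers(1, max(2, len(span) // 3)))
            if hi > lo:
                cds = GenomicInterval(chrom, lo, hi, strand)
        genes.append(
            GeneModel(f"g{g}", [TranscriptModel(t.id, chrom, strand, t.exons, cds=cds)])
        )
    sizes = {f"chr{i + 1}": chrom_len for i in range(n_chroms)}
    return Annotation(genes, sizes)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_labels(annotation, sizes, promoter_bp=2000):
    """Independent per-base region labeling: boolean class masks combined
    by priority with np.select, unlike the implementation's incremental
    priority painting."""
    classes = ("coding_exon", "utr5", "utr3", "intron", "promoter", "intergenic")
    out = {}
    for chrom, n in sizes.items():
        masks = {cls: np.zeros(n, dtype=bool) for cls in classes}
        for gene in annotation:
            if gene.chrom != chrom:
                continue
            span = gene.span
            windows = []
            if gene.strand != "-":
                windows.append((span.start - promoter_bp, span.start))
            if gene.strand != "+":
                windows.append((span.end, span.end + promoter_bp))
            for s, e in windows:
                masks["promoter"][max(0, s) : min(n, e)] = True
            for t in gene.transcripts:
                for intron in t.introns():
                    masks["intron"][intron.start : intron.end] = True
                left = "utr5" if t.strand != "-" else "utr3"
                right = "utr3" if t.strand != "-" else "utr5"
                for ex in t.exons:
                    if t.cds is None:
                        masks["coding_exon"][ex.start : ex.end] = True
                        continue
                    if ex.start < t.cds.start:
                        masks[left][ex.start : min(ex.end, t.cds.start)] = True
                    if ex.end > t.cds.end:
                        masks[right][max(ex.start, t.cds.end) : ex.end] = True
                    s, e = max(ex.start, t.cds.start), min(ex.end, t.cds.end)
                    if e > s:
                        masks["coding_exon"][s:e] = True
        label = np.select(
            [masks[c] for c in classes[:5]], list(range(5)), default=5
        )
        out[chrom] = np.array(classes, dtype=object)[label]
    return out
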