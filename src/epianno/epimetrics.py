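"""Genome partition, peak-distribution and meta-gene profiling.

The genome is tiled exhaustively into six regional classes — promoter,
5' UTR, 3' UTR, coding exon, intron, intergenic — and ChIP-seq peak mass
is apportioned base-by-base over those classes. Peaks are tied to genes
through a strand-aware window: the gene body plus a fixed stretch
(default 2 kb) upstream of the TSS. Meta-gene profiles average a coverage
track over genes after rescaling each gene body to a common number of
bins, with fixed-width flanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .intervals import (
    FORWARD,
    REVERSE,
    UNKNOWN,
    Annotation,
    GeneModel,
    GenomicInterval,
)
from .io import CoverageTrack, ExpressionMatrix, PeakSet

REGION_CLASSES = (
    "coding_exon",
    "utr5",
    "utr3",
    "intron",
    "promoter",
    "intergenic",
)
# per-base precedence when classes overlap; the genic classes outrank the
# promoter so "intergenic vs genic" stays conservative
_PRIORITY = {
    "intergenic": 0,
    "promoter": 1,
    "intron": 2,
    "utr3": 3,
    "utr5": 4,
    "coding_exon": 5,
}
_CODE_TO_CLASS = {v: k for k, v in _PRIORITY.items()}


class RegionPartition:
    """An exhaustive per-base labeling of a genome into six classes.

    Stored as one label array per chromosome (uint8 priority codes);
    ``runs`` re-expresses a chromosome as maximal constant-label runs.
    """

    def __init__(self, labels: dict[str, np.ndarray], promoter_bp: int):
        self.labels = labels
        self.promoter_bp = promoter_bp

    def class_bp(self) -> dict[str, int]:
        counts = {cls: 0 for cls in REGION_CLASSES}
        for arr in self.labels.values():
            binned = np.bincount(arr, minlength=len(_PRIORITY))
            for code, n in enumerate(binned):
                counts[_CODE_TO_CLASS[code]] += int(n)
        return counts

    def total_bp(self) -> int:
        return sum(arr.size for arr in self.labels.values())

    def runs(self, chrom: str) -> list[tuple[int, int, str]]:
        arr = self.labels[chrom]
        if arr.size == 0:
            return []
        breaks = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [arr.size]])
        return [
            (int(s), int(e), _CODE_TO_CLASS[int(arr[s])])
            for s, e in zip(starts, ends)
        ]

    def label_at(self, chrom: str, pos: int) -> str:
        return _CODE_TO_CLASS[int(self.labels[chrom][pos])]


def _paint(arr: np.ndarray, start: int, end: int, code: int) -> None:
    """Raise bases in [start, end) to ``code`` where the code is higher."""
    s, e = max(0, start), min(arr.size, end)
    if e > s:
        seg = arr[s:e]
        np.maximum(seg, code, out=seg)


def build_region_partition(
    annotation: Annotation,
    chrom_sizes: Optional[dict[str, int]] = None,
    promoter_bp: int = 2000,
) -> RegionPartition:
    """Label every base of the genome with its highest-priority class.

    UTRs are derived from exon-minus-CDS on the strand-appropriate side of
    the CDS; transcripts without a CDS contribute their exons to the
    coding-exon class. The promoter is the ``promoter_bp`` window upstream
    of each gene TSS (strand-aware, clipped at chromosome bounds) and only
    claims bases no genic class covers. An unknown-strand gene gets
    promoter windows on both sides, since its TSS side is undetermined.
    """
    sizes = chrom_sizes if chrom_sizes is not None else annotation.chrom_sizes
    labels = {
        chrom: np.zeros(size, dtype=np.uint8) for chrom, size in sizes.items()
    }
    for gene in annotation:
        arr = labels[gene.chrom]
        span = gene.span
        if gene.strand == REVERSE:
            _paint(arr, span.end, span.end + promoter_bp, _PRIORITY["promoter"])
        elif gene.strand == FORWARD:
            _paint(arr, span.start - promoter_bp, span.start, _PRIORITY["promoter"])
        else:
            _paint(arr, span.start - promoter_bp, span.start, _PRIORITY["promoter"])
            _paint(arr, span.end, span.end + promoter_bp, _PRIORITY["promoter"])
        for t in gene.transcripts:
            for intron in t.introns():
                _paint(arr, intron.start, intron.end, _PRIORITY["intron"])
            if t.cds is None:
                for ex in t.exons:
                    _paint(arr, ex.start, ex.end, _PRIORITY["coding_exon"])
                continue
            left_utr = "utr5" if t.strand != REVERSE else "utr3"
            right_utr = "utr3" if t.strand != REVERSE else "utr5"
            for ex in t.exons:
                lo, hi = ex.start, ex.end
                if lo < t.cds.start:
                    _paint(arr, lo, min(hi, t.cds.start), _PRIORITY[left_utr])
                if hi > t.cds.end:
                    _paint(arr, max(lo, t.cds.end), hi, _PRIORITY[right_utr])
                s, e = max(lo, t.cds.start), min(hi, t.cds.end)
                if e > s:
                    _paint(arr, s, e, _PRIORITY["coding_exon"])
    return RegionPartition(labels, promoter_bp)


def region_fractions(partition: RegionPartition) -> dict[str, float]:
    """Percent of the genome in each class; sums to 100."""
    total = partition.total_bp()
    if total == 0:
        raise ValueError("empty genome")
    return {
        cls: 100.0 * bp / total for cls, bp in partition.class_bp().items()
    }


def peak_region_distribution(
    peaks: PeakSet, partition: RegionPartition
) -> dict[str, float]:
    """Percent of total peak bases falling in each regional class.

    Each peak's bases are tallied against the classes covering them, so
    the result is a true partition of peak mass summing to 100. Peaks
    extending beyond chromosome bounds are clipped with a warning.
    """
    counts = np.zeros(len(_PRIORITY), dtype=np.int64)
    for p in peaks:
        iv = p.interval
        arr = partition.labels.get(iv.chrom)
        if arr is None:
            warnings.warn(f"peak on unknown chromosome {iv.chrom}; skipped")
            continue
        s, e = max(0, iv.start), min(arr.size, iv.end)
        if (s, e) != (iv.start, iv.end):
            warnings.warn(
                f"peak [{iv.start},{iv.end}) clipped to {iv.chrom} bounds"
            )
        if e > s:
            counts += np.bincount(arr[s:e], minlength=len(_PRIORITY))
    total = counts.sum()
    if total == 0:
        raise ValueError("no peak bases inside the genome")
    return {
        _CODE_TO_CLASS[code]: 100.0 * counts[code] / total
        for code in range(len(_PRIORITY))
    }


# ---------------------------------------------------------------------------
# Peak-to-gene association


def gene_window(gene: GeneModel, upstream_bp: int = 2000) -> GenomicInterval:
    """Gene body plus the strand-aware upstream window, clipped at 0.

    Unknown-strand genes are extended on both sides.
    """
    span = gene.span
    if gene.strand == FORWARD:
        start, end = span.start - upstream_bp, span.end
    elif gene.strand == REVERSE:
        start, end = span.start, span.end + upstream_bp
    else:
        start, end = span.start - upstream_bp, span.end + upstream_bp
    return GenomicInterval(gene.chrom, max(0, start), end)


def associate_peaks_to_genes(
    peaks: PeakSet,
    annotation: Annotation,
    upstream_bp: int = 2000,
) -> dict[str, list]:
    """Genes whose body-plus-upstream window overlaps >=1 peak base.

    Returns gene id -> supporting peaks; a peak may associate with
    several genes. Genes with no supporting peak are absent from the map.
    """
    by_chrom: dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    out: dict[str, list] = {}
    for gene in annotation:
        window = gene_window(gene, upstream_bp)
        hits = [
            p
            for p in by_chrom.get(gene.chrom, [])
            if min(p.interval.end, window.end) - max(p.interval.start, window.start)
            >= 1
        ]
        if hits:
            out[gene.id] = hits
    return out


# ---------------------------------------------------------------------------
# Coverage normalization and meta-gene profiles


def normalize_per_million(
    track: CoverageTrack, mapped_reads: int
) -> CoverageTrack:
    """Divide every run value by millions of mapped reads.

    Refuses to normalize an already-normalized track.
    """
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be positive")
    if track.normalization_state != "raw":
        raise ValueError("track is already normalized per million")
    factor = mapped_reads / 1e6
    runs = {
        chrom: [(s, e, v / factor) for s, e, v in track.runs(chrom)]
        for chrom in track.chroms
    }
    return CoverageTrack(runs, normalization_state="per-million")


@dataclass
class MetaGeneProfile:
    """Mean signal per bin across genes: flank | scaled body | flank."""

    values: np.ndarray
    flank_bins: int
    body_bins: int
    n_genes: int
    flank_bp: int
    label: str = ""

    @property
    def is_empty(self) -> bool:
        return self.n_genes == 0

    def tss_bin_value(self) -> float:
        """Signal in the first body bin (the TSS-proximal bin)."""
        return float(self.values[self.flank_bins])


def _interval_means(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Mean of a per-base step function over consecutive [edges[i], edges[i+1]).

    Edges may be fractional; partial bases contribute proportionally, which
    keeps short gene bodies well-defined for any bin count.
    """
    cum = np.concatenate([[0.0], np.cumsum(values)])
    pos = np.arange(cum.size, dtype=np.float64)

    def integral(x: np.ndarray) -> np.ndarray:
        return np.interp(x, pos, cum)

    areas = integral(edges[1:]) - integral(edges[:-1])
    widths = np.diff(edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(widths > 0, areas / widths, 0.0)
    return means


def _gene_profile(
    track: CoverageTrack,
    gene: GeneModel,
    flank_bp: int,
    body_bins: int,
    flank_bin_bp: int,
) -> np.ndarray:
    span = gene.span
    window = track.dense(gene.chrom, span.start - flank_bp, span.end + flank_bp)
    if gene.strand == REVERSE:
        window = window[::-1]
    flank_bins = flank_bp // flank_bin_bp
    up = window[:flank_bp].reshape(flank_bins, flank_bin_bp).mean(axis=1)
    down = window[-flank_bp:].reshape(flank_bins, flank_bin_bp).mean(axis=1)
    body = window[flank_bp : window.size - flank_bp]
    edges = np.linspace(0.0, body.size, body_bins + 1)
    mids = _interval_means(body, edges)
    return np.concatenate([up, mids, down])


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    flank_bp: int = 1000,
    body_bins: int = 100,
    flank_bin_bp: int = 50,
    label: str = "",
) -> MetaGeneProfile:
    """Average coverage over genes: fixed flanks, length-scaled body.

    Reverse-strand genes are flipped so bin 0 is always 5'-most; flank
    bases beyond the chromosome read as 0. Bodies shorter than
    ``body_bins`` are handled by fractional-base bin means.
    """
    if flank_bp % flank_bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of flank_bin_bp")
    flank_bins = flank_bp // flank_bin_bp
    n_bins = 2 * flank_bins + body_bins
    if not genes:
        return MetaGeneProfile(
            np.zeros(n_bins), flank_bins, body_bins, 0, flank_bp, label
        )
    acc = np.zeros(n_bins, dtype=np.float64)
    for gene in genes:
        acc += _gene_profile(track, gene, flank_bp, body_bins, flank_bin_bp)
    return MetaGeneProfile(
        acc / len(genes), flank_bins, body_bins, len(genes), flank_bp, label
    )


def quantile_groups(
    genes: Sequence[GeneModel],
    expr: ExpressionMatrix,
    sample: str,
    n_quantiles: int = 9,
) -> tuple[list[list[GeneModel]], list[GeneModel]]:
    """Split genes into expression quantile groups plus a not-expressed group.

    Genes with FPKM > 0 are ranked ascending (ties broken by gene id) and
    cut into ``n_quantiles`` equal-count groups; when the count does not
    divide evenly the remainder goes to the lowest-expression groups.
    FPKM = 0 genes (including genes absent from the matrix) form the
    not-expressed group. Group order is lowest to highest expression.
    """
    if sample not in expr.samples:
        raise KeyError(f"sample {sample!r} not in expression matrix")
    expressed = []
    silent = []
    for gene in genes:
        fpkm = expr.fpkm(gene.id, sample)
        if fpkm > 0:
            expressed.append((fpkm, gene.id, gene))
        else:
            silent.append(gene)
    expressed.sort(key=lambda item: (item[0], item[1]))
    n = len(expressed)
    base, rem = divmod(n, n_quantiles)
    groups: list[list[GeneModel]] = []
    pos = 0
    for q in range(n_quantiles):
        size = base + (1 if q < rem else 0)
        groups.append([g for _, _, g in expressed[pos : pos + size]])
        pos += size
    return groups, silent


def profiles_by_expression_quantile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    expr: ExpressionMatrix,
    sample: str,
    n_quantiles: int = 9,
    flank_bp: int = 1000,
    body_bins: int = 100,
    flank_bin_bp: int = 50,
) -> tuple[list[MetaGeneProfile], MetaGeneProfile]:
    """One meta-gene profile per expression quantile plus not-expressed.

    Quantile profiles are ordered lowest to highest expression; empty
    groups yield profiles flagged empty (``n_genes == 0``).
    """
    groups, silent = quantile_groups(genes, expr, sample, n_quantiles)
    profiles = [
        metagene_profile(
            track, grp, flank_bp, body_bins, flank_bin_bp, label=f"q{q + 1}"
        )
        for q, grp in enumerate(groups)
    ]
    silent_profile = metagene_profile(
        track, silent, flank_bp, body_bins, flank_bin_bp, label="not_expressed"
    )
    return profiles, silent_profile
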