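"""Genomic interval and gene-model primitives.

All coordinates are 0-based half-open ``[start, end)``. GTF's 1-based
inclusive convention is converted at the I/O boundary (:mod:`epianno.io`)
and nowhere else. Strand is one of ``"+"``, ``"-"`` or ``"."`` (unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

FORWARD = "+"
REVERSE = "-"
UNKNOWN = "."
STRANDS = (FORWARD, REVERSE, UNKNOWN)


class ValidationError(ValueError):
    """Raised when a genomic object violates its structural invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval [{self.start},{self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def interval_overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class TranscriptModel:
    """A transcript: an ordered chain of non-overlapping exons.

    ``transcript_length`` is the genomic span (first exon start to last
    exon end), not the summed exon length; ``exonic_length`` gives the
    latter.
    """

    id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: Optional[GenomicInterval] = None
    source_samples: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.id}: no exons")
        if self.strand not in STRANDS:
            raise ValidationError(f"transcript {self.id}: bad strand {self.strand!r}")
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValidationError(
                    f"transcript {self.id}: exon on {ex.chrom}, transcript on {self.chrom}"
                )
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise ValidationError(
                    f"transcript {self.id}: exons out of order or overlapping "
                    f"([{prev.start},{prev.end}) then [{nxt.start},{nxt.end}))"
                )
        if self.cds is not None:
            if self.cds.chrom != self.chrom:
                raise ValidationError(f"transcript {self.id}: CDS on wrong chromosome")
            if self.cds.start < self.span.start or self.cds.end > self.span.end:
                raise ValidationError(f"transcript {self.id}: CDS outside span")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def transcript_length(self) -> int:
        return self.exons[-1].end - self.exons[0].start

    @property
    def exonic_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        """Intervals between consecutive exons (empty gaps excluded)."""
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start > prev.end:
                out.append(GenomicInterval(self.chrom, prev.end, nxt.start, self.strand))
        return out


def exonic_overlap_bp(t1: TranscriptModel, t2: TranscriptModel) -> int:
    """Total exon-to-exon overlap between two transcripts, in bp.

    Exon chains are sorted, so a linear merge suffices.
    """
    if t1.chrom != t2.chrom:
        return 0
    total = 0
    i = j = 0
    e1, e2 = t1.exons, t2.exons
    while i < len(e1) and j < len(e2):
        a, b = e1[i], e2[j]
        total += max(0, min(a.end, b.end) - max(a.start, b.start))
        if a.end <= b.end:
            i += 1
        else:
            j += 1
    return total


@dataclass
class GeneModel:
    """A gene: one or more transcripts on a single chromosome.

    The gene span is the union span of its transcripts, and the TSS is
    strand-dependent: span start on the forward strand, span end on the
    reverse strand (unknown strand falls back to span start).
    """

    id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.id}: no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) != 1:
            raise ValidationError(f"gene {self.id}: transcripts span chromosomes {chroms}")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        known = {t.strand for t in self.transcripts} - {UNKNOWN}
        if len(known) == 1:
            return next(iter(known))
        return UNKNOWN

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def tss(self) -> int:
        span = self.span
        return span.end if self.strand == REVERSE else span.start


class Annotation:
    """A gene set with chromosome sizes and an overlap index.

    The index is an interval tree per chromosome over gene spans; queries
    return exactly what a linear scan over all genes would.
    """

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: dict[str, int]):
        self.genes: list[GeneModel] = sorted(
            genes, key=lambda g: (g.chrom, g.span.start, g.id)
        )
        self.chrom_sizes = dict(chrom_sizes)
        for gene in self.genes:
            size = self.chrom_sizes.get(gene.chrom)
            if size is None:
                raise ValidationError(
                    f"gene {gene.id}: chromosome {gene.chrom} not in chrom sizes"
                )
            if gene.span.end > size:
                raise ValidationError(
                    f"gene {gene.id}: span end {gene.span.end} beyond "
                    f"{gene.chrom} length {size}"
                )
        self._by_id = {g.id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValidationError("duplicate gene ids")
        self._trees: dict[str, IntervalTree] = {}
        for gene in self.genes:
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            tree.addi(gene.span.start, gene.span.end, gene.id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gene in self.genes:
            yield from gene.transcripts

    def query_overlapping(self, iv: GenomicInterval) -> set[str]:
        """Ids of genes whose span overlaps ``iv`` by at least one base."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(iv.start, iv.end)}
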