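"""Readers and writers for the plain-text formats the pipeline exchanges.

GTF (1-based inclusive), BED6 and ENCODE narrowPeak, bedGraph, chrom.sizes
and a transcript-by-sample FPKM TSV. Every reader either returns a fully
validated object or raises :class:`FormatError` naming the offending line;
nothing is silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .intervals import (
    FORWARD,
    REVERSE,
    UNKNOWN,
    Annotation,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
)


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column ``name<TAB>length`` file."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'name length', got {line!r}")
        name, length = parts
        if name in sizes:
            raise FormatError(f"{path}:{lineno}: duplicate chromosome {name}")
        try:
            sizes[name] = int(length)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad length {length!r}") from exc
        if sizes[name] <= 0:
            raise FormatError(f"{path}:{lineno}: non-positive length for {name}")
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")


# ---------------------------------------------------------------------------
# GTF


def _first_attr(feature, key: str) -> Optional[str]:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def read_gtf(
    path: str | Path,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> Annotation:
    """Parse a GTF into an :class:`Annotation`.

    Exon features are grouped by ``transcript_id`` and transcripts by
    ``gene_id``; a CDS feature spanning region is attached to its
    transcript when present. Both ``key "value";`` and ``key=value``
    attribute styles are accepted (assembler outputs vary). Coordinates
    are converted from GTF's 1-based inclusive to internal 0-based
    half-open. When ``chrom_sizes`` is given, features beyond chromosome
    bounds are rejected; otherwise sizes are inferred as the maximum
    coordinate seen per chromosome.
    """
    # transcript_id -> accumulated state
    exons: dict[str, list[GenomicInterval]] = {}
    cds_bounds: dict[str, list[int]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (chrom, strand, gene_id)
    order: list[str] = []
    samples: dict[str, set[str]] = {}

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.count("\t") < 8:
            raise FormatError(f"{path}:{lineno}: fewer than 9 tab-separated columns")
        try:
            feat = feature_from_line(line)
        except Exception as exc:
            raise FormatError(f"{path}:{lineno}: unparseable GTF line: {exc}") from exc
        ftype = feat.featuretype.lower()
        if ftype not in ("exon", "cds"):
            continue
        tid = _first_attr(feat, "transcript_id")
        gid = _first_attr(feat, "gene_id")
        if tid is None:
            raise FormatError(f"{path}:{lineno}: missing transcript_id attribute")
        if gid is None:
            gid = tid
        start0, end0 = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        if start0 < 0 or end0 <= start0:
            raise FormatError(f"{path}:{lineno}: bad coordinates {feat.start}..{feat.end}")
        if chrom_sizes is not None:
            size = chrom_sizes.get(feat.seqid)
            if size is None:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {feat.seqid}")
            if end0 > size:
                raise FormatError(
                    f"{path}:{lineno}: feature end {end0} beyond {feat.seqid} length {size}"
                )
        strand = feat.strand if feat.strand in (FORWARD, REVERSE) else UNKNOWN
        if tid not in meta:
            meta[tid] = (feat.seqid, strand, gid)
            order.append(tid)
        elif meta[tid][0] != feat.seqid:
            raise FormatError(f"{path}:{lineno}: transcript {tid} spans chromosomes")
        if ftype == "exon":
            exons.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, start0, end0, strand)
            )
        else:
            lo, hi = cds_bounds.setdefault(tid, [start0, end0])
            cds_bounds[tid] = [min(lo, start0), max(hi, end0)]
        support = _first_attr(feat, "support_tissues")
        if support:
            samples.setdefault(tid, set()).update(support.split(","))

    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in order:
        chrom, strand, gid = meta[tid]
        if tid not in exons:
            raise FormatError(f"{path}: transcript {tid} has no exon features")
        exon_list = sorted(exons[tid], key=lambda iv: iv.start)
        cds = None
        if tid in cds_bounds:
            lo, hi = cds_bounds[tid]
            cds = GenomicInterval(chrom, lo, hi, strand)
        try:
            model = TranscriptModel(
                tid, chrom, strand, exon_list, cds=cds,
                source_samples=samples.get(tid, set()),
            )
        except ValidationError as exc:
            raise FormatError(f"{path}: transcript {tid}: {exc}") from exc
        if gid not in genes:
            gene_order.append(gid)
        genes.setdefault(gid, []).append(model)

    if chrom_sizes is None:
        chrom_sizes = {}
        for models in genes.values():
            for t in models:
                chrom_sizes[t.chrom] = max(chrom_sizes.get(t.chrom, 0), t.span.end)
    return Annotation(
        [GeneModel(gid, genes[gid]) for gid in gene_order], chrom_sizes
    )


def write_gtf(
    transcripts: Iterable[TranscriptModel] | Annotation,
    path: str | Path,
    source: str = "epianno",
) -> None:
    """Emit transcripts as GTF, one exon line per exon.

    Output order is (chrom, start, id), so identical inputs give a
    bit-identical file. ``source_samples`` round-trips through a
    ``support_tissues`` attribute.
    """
    if isinstance(transcripts, Annotation):
        gene_of = {
            t.id: g.id for g in transcripts.genes for t in g.transcripts
        }
        models = list(transcripts.transcripts())
    else:
        models = list(transcripts)
        gene_of = {t.id: t.id for t in models}
    models.sort(key=lambda t: (t.chrom, t.span.start, t.id))
    with open(path, "w") as fh:
        for t in models:
            attrs = f'gene_id "{gene_of[t.id]}"; transcript_id "{t.id}";'
            if t.source_samples:
                attrs += f' support_tissues "{",".join(sorted(t.source_samples))}";'
            rows = [("exon", ex.start, ex.end) for ex in t.exons]
            if t.cds is not None:
                rows.append(("CDS", t.cds.start, t.cds.end))
            for ftype, s, e in rows:
                fh.write(
                    f"{t.chrom}\t{source}\t{ftype}\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Peaks


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float
    center: int

    def __post_init__(self) -> None:
        if not self.interval.start <= self.center < self.interval.end:
            raise ValidationError(
                f"peak center {self.center} outside "
                f"[{self.interval.start},{self.interval.end})"
            )
        if self.score < 0:
            raise ValidationError(f"negative peak score {self.score}")


@dataclass
class PeakSet:
    """Scored peak intervals from one tissue, each with a defined center."""

    peaks: list[Peak]
    tissue_label: str

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def read_peaks(
    path: str | Path, dialect: str, tissue_label: str
) -> PeakSet:
    """Read BED6 or ENCODE narrowPeak peak calls.

    BED6 has no summit, so the center is the floor midpoint. narrowPeak's
    10th column is the summit offset from peak start; an offset of -1
    (summit not called) falls back to the midpoint.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    want = 6 if dialect == "bed6" else 10
    peaks: list[Peak] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < want:
            raise FormatError(
                f"{path}:{lineno}: {dialect} needs {want} columns, got {len(cols)}"
            )
        chrom, start, end = cols[0], int(cols[1]), int(cols[2])
        score = float(cols[4]) if cols[4] != "." else 0.0
        if dialect == "bed6":
            center = (start + end) // 2
        else:
            offset = int(cols[9])
            if offset == -1:
                center = (start + end) // 2
            else:
                center = start + offset
                if not start <= center < end:
                    raise FormatError(
                        f"{path}:{lineno}: summit offset {offset} outside peak"
                    )
        try:
            peaks.append(Peak(GenomicInterval(chrom, start, end), score, center))
        except ValidationError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(peaks, tissue_label)


def write_peaks_bed6(peakset: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peakset):
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{peakset.tissue_label}_peak_{i}\t{p.score:g}\t.\n"
            )


def write_peaks_narrowpeak(peakset: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peakset):
            offset = p.center - p.interval.start
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{peakset.tissue_label}_peak_{i}\t{p.score:g}\t.\t0\t-1\t-1\t{offset}\n"
            )


# ---------------------------------------------------------------------------
# Coverage


class CoverageTrack:
    """A stepwise per-base signal: sorted non-overlapping (start,end,value) runs.

    Any base not covered by a run has value 0. Lookup and range means use
    binary search over run boundaries.
    """

    def __init__(
        self,
        runs: dict[str, Sequence[tuple[int, int, float]]],
        normalization_state: str = "raw",
    ):
        if normalization_state not in ("raw", "per-million"):
            raise ValueError(f"bad normalization state {normalization_state!r}")
        self.normalization_state = normalization_state
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, chrom_runs in runs.items():
            rs = sorted(chrom_runs)
            for (s1, e1, v1), (s2, e2, v2) in zip(rs, rs[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"{chrom}: overlapping runs [{s1},{e1}) and [{s2},{e2})"
                    )
            starts = np.array([r[0] for r in rs], dtype=np.int64)
            ends = np.array([r[1] for r in rs], dtype=np.int64)
            values = np.array([r[2] for r in rs], dtype=np.float64)
            if np.any(values < 0):
                raise ValidationError(f"{chrom}: negative coverage value")
            if np.any(ends <= starts):
                raise ValidationError(f"{chrom}: empty run")
            self._starts[chrom], self._ends[chrom], self._values[chrom] = (
                starts, ends, values,
            )

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def runs(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._starts:
            return []
        return list(
            zip(
                self._starts[chrom].tolist(),
                self._ends[chrom].tolist(),
                self._values[chrom].tolist(),
            )
        )

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._starts:
            return 0.0
        i = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        if i >= 0 and pos < self._ends[chrom][i]:
            return float(self._values[chrom][i])
        return 0.0

    def dense(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); out-of-track bases are 0.

        ``start`` may be negative and ``end`` may exceed the chromosome:
        those bases read as 0, which is what flank extraction wants.
        """
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self._starts or end <= start:
            return out
        starts, ends, values = (
            self._starts[chrom], self._ends[chrom], self._values[chrom],
        )
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if e > s:
                out[s - start : e - start] = values[i]
        return out

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return float(self.dense(chrom, start, end).mean())

    def total_area(self) -> float:
        return float(
            sum(
                ((self._ends[c] - self._starts[c]) * self._values[c]).sum()
                for c in self._starts
            )
        )


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """4-column bedGraph; runs may arrive unsorted but must not overlap."""
    runs: dict[str, list[tuple[int, int, float]]] = {}
    lines_of: dict[str, list[int]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) != 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom = cols[0]
        try:
            start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        runs.setdefault(chrom, []).append((start, end, value))
        lines_of.setdefault(chrom, []).append(lineno)
    for chrom, chrom_runs in runs.items():
        order = sorted(range(len(chrom_runs)), key=lambda i: chrom_runs[i])
        for i, j in zip(order, order[1:]):
            if chrom_runs[j][0] < chrom_runs[i][1]:
                raise FormatError(
                    f"{path}: overlapping runs on {chrom} "
                    f"(lines {lines_of[chrom][i]} and {lines_of[chrom][j]})"
                )
    try:
        return CoverageTrack(runs)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for start, end, value in track.runs(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Expression


class ExpressionMatrix:
    """Transcript-by-sample FPKM values backed by a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated transcript ids: {dupes}")
        df = df.fillna(0.0).astype(float)
        if (df.values < 0).any():
            raise ValidationError("negative FPKM values")
        self.df = df

    @property
    def transcripts(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def fpkm(self, transcript: str, sample: str) -> float:
        """Missing transcripts read as 0 by convention."""
        if transcript not in self.df.index:
            return 0.0
        return float(self.df.at[transcript, sample])


def read_expression(path: str | Path) -> ExpressionMatrix:
    """TSV with a sample-id header row; first column is the transcript id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return ExpressionMatrix(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="transcript_id")
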