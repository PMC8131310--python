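"""Synthetic fixtures emulating the pipeline's inputs.

A toy genome is laid out feature-by-feature along each chromosome: known
genes (with CDS and UTRs) and planted novel transcripts, separated by
intergenic gaps wide enough that one feature's promoter-proximal peak
cannot be confused with its neighbour's. Per-sample assemblies contain
fragments of the known genes plus whichever planted novels survive
dropout, with optional exon-boundary jitter; each tissue gets one
H3K4me3-like peak per expressed transcript, centred a fixed offset
upstream of the TSS (strand-aware), plus optional decoy peaks in
intergenic space. Coverage tracks carry a 5'-weighted kernel per
expressed transcript scaled by its FPKM, so TSS enrichment grows with
expression. Everything derives from one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    FORWARD,
    REVERSE,
    UNKNOWN,
    Annotation,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from .io import (
    CoverageTrack,
    ExpressionMatrix,
    Peak,
    PeakSet,
    write_bedgraph,
    write_chrom_sizes,
    write_expression,
    write_gtf,
    write_peaks_narrowpeak,
)


class ConfigError(ValueError):
    """The requested fixture cannot fit in the requested genome."""


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the fixture generator.

    The defaults describe the desk-scale study conditions: ten RNA-seq
    samples with 30% per-sample dropout of each planted novel, three
    tissues with TSS-anchored peaks 500 bp upstream of each expressed
    transcript, no boundary jitter and no decoy peaks.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 400_000
    n_known_genes: int = 60
    n_novel_transcripts: int = 40
    known_exon_count: tuple[int, int] = (1, 5)
    novel_exon_count: tuple[int, int] = (1, 3)
    exon_length: tuple[int, int] = (150, 600)
    intron_length: tuple[int, int] = (100, 800)
    intergenic_gap: tuple[int, int] = (3000, 6000)
    n_samples: int = 10
    tissues: tuple[str, ...] = ("leaf", "stem", "root")
    dropout: float = 0.3
    jitter_sd: float = 0.0
    peak_offset: int = 500
    peak_width: int = 1000
    decoy_fraction: float = 0.0
    fpkm_log2_range: tuple[float, float] = (0.0, 8.0)
    known_silent_prob: float = 0.2
    fragment_prob: float = 0.8
    coverage_bin: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.dropout <= 1:
            raise ConfigError("dropout must be in [0,1]")
        if not 0 <= self.decoy_fraction <= 1:
            raise ConfigError("decoy_fraction must be in [0,1]")
        if min(self.n_chroms, self.chrom_length, self.n_samples) <= 0:
            raise ConfigError("counts must be positive")
        if self.peak_width <= 0 or self.peak_offset < 0:
            raise ConfigError("bad peak geometry")


@dataclass
class TruthSet:
    """What was planted: novels with true strands and tissue patterns."""

    novels: list[TranscriptModel]
    tissues_of: dict[str, set[str]]  # novel id -> tissues where expressed
    peaks: dict[str, PeakSet]  # tissue -> planted (non-decoy) peaks
    expression: ExpressionMatrix

    def specificity_of(self, novel_id: str, n_tissues: int) -> str:
        k = len(self.tissues_of[novel_id])
        if k == n_tissues:
            return "all-tissues"
        if k == 1:
            return "single-tissue"
        return "subset" if k > 0 else "none"


@dataclass
class Fixture:
    """An in-memory fixture plus the truth used to make it."""

    config: SynthConfig
    known: Annotation
    assemblies: list[list[TranscriptModel]]  # one per sample
    sample_names: list[str]
    peaksets: dict[str, PeakSet]  # tissue -> peaks incl. decoys
    tracks: dict[str, CoverageTrack]
    expression: ExpressionMatrix
    truth: TruthSet


def _make_transcript(
    rng: np.random.Generator,
    tid: str,
    chrom: str,
    start: int,
    n_exons: int,
    exon_len: tuple[int, int],
    intron_len: tuple[int, int],
    strand: str,
    with_cds: bool,
) -> TranscriptModel:
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(exon_len[0], exon_len[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(intron_len[0], intron_len[1] + 1))
    cds = None
    if with_cds:
        span_start, span_end = exons[0].start, exons[-1].end
        utr5 = int(rng.integers(30, max(31, len(exons[0]) // 2)))
        utr3 = int(rng.integers(30, max(31, len(exons[-1]) // 2)))
        lo, hi = span_start + utr5, span_end - utr3
        if hi > lo:
            cds = GenomicInterval(chrom, lo, hi, strand)
    return TranscriptModel(tid, chrom, strand, exons, cds=cds)


def _layout_genome(cfg: SynthConfig, rng: np.random.Generator):
    """Place known genes and novels along chromosomes, left to right.

    Raises :class:`ConfigError` before anything is emitted if the
    features cannot fit.
    """
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    # round-robin feature assignment keeps chromosomes balanced
    kinds = ["known"] * cfg.n_known_genes + ["novel"] * cfg.n_novel_transcripts
    rng.shuffle(kinds)
    per_chrom: dict[str, list[str]] = {c: [] for c in chrom_names}
    for i, kind in enumerate(kinds):
        per_chrom[chrom_names[i % cfg.n_chroms]].append(kind)

    margin = max(3000, cfg.peak_offset + cfg.peak_width)
    known: list[TranscriptModel] = []
    novels: list[TranscriptModel] = []
    gaps: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    n_known = n_novel = 0
    for chrom in chrom_names:
        cursor = margin
        gap_start = 0
        for kind in per_chrom[chrom]:
            gaps[chrom].append((gap_start, cursor))
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            if kind == "known":
                n_exons = int(
                    rng.integers(cfg.known_exon_count[0], cfg.known_exon_count[1] + 1)
                )
                t = _make_transcript(
                    rng, f"KNOWN_{n_known:05d}", chrom, cursor, n_exons,
                    cfg.exon_length, cfg.intron_length, strand, with_cds=True,
                )
                known.append(t)
                n_known += 1
            else:
                n_exons = int(
                    rng.integers(cfg.novel_exon_count[0], cfg.novel_exon_count[1] + 1)
                )
                t = _make_transcript(
                    rng, f"NOVEL_{n_novel:05d}", chrom, cursor, n_exons,
                    cfg.exon_length, cfg.intron_length, strand, with_cds=False,
                )
                novels.append(t)
                n_novel += 1
            gap_start = t.span.end
            cursor = t.span.end + int(
                rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1)
            )
        if gap_start + margin > cfg.chrom_length:
            raise ConfigError(
                f"features overflow {chrom}: need {gap_start + margin} bp, "
                f"have {cfg.chrom_length}; increase chrom_length or n_chroms"
            )
        gaps[chrom].append((gap_start, cfg.chrom_length))
    sizes = {c: cfg.chrom_length for c in chrom_names}
    return known, novels, sizes, gaps


def _tss(t: TranscriptModel) -> int:
    return t.span.end if t.strand == REVERSE else t.span.start


def _plant_peak(t: TranscriptModel, cfg: SynthConfig, score: float) -> Peak:
    tss = _tss(t)
    center = tss - cfg.peak_offset if t.strand != REVERSE else tss + cfg.peak_offset
    half = cfg.peak_width // 2
    start = max(0, center - half)
    end = start + cfg.peak_width
    return Peak(GenomicInterval(t.chrom, start, end), score, center)


def _jitter_exons(
    exons: Sequence[GenomicInterval], sd: float, rng: np.random.Generator
) -> list[GenomicInterval]:
    if sd <= 0:
        return list(exons)
    out = []
    prev_end = -(10**9)
    for ex in exons:
        ds = int(round(rng.normal(0, sd)))
        de = int(round(rng.normal(0, sd)))
        start = max(ex.start + ds, prev_end + 1, 0)
        end = max(ex.end + de, start + 1)
        out.append(GenomicInterval(ex.chrom, start, end, ex.strand))
        prev_end = end
    return out


def _fragment(
    gene: TranscriptModel, rng: np.random.Generator, tid: str
) -> TranscriptModel:
    """A partial reassembly of a known transcript (sub-chain of exons)."""
    n = gene.exon_count
    i = int(rng.integers(0, n))
    j = int(rng.integers(i, n)) + 1
    exons = list(gene.exons[i:j])
    # truncate the outer boundaries a little, as assemblers do
    first, last = exons[0], exons[-1]
    trim_s = int(rng.integers(0, max(1, len(first) // 3)))
    trim_e = int(rng.integers(0, max(1, len(last) // 3)))
    exons[0] = GenomicInterval(first.chrom, first.start + trim_s, first.end, first.strand)
    shrunk = GenomicInterval(last.chrom, last.start, last.end - trim_e, last.strand) \
        if len(last) - trim_e > 0 else last
    exons[-1] = shrunk
    return TranscriptModel(tid, gene.chrom, gene.strand, exons)


def simulate(cfg: SynthConfig) -> Fixture:
    """Generate the full fixture in memory, reproducibly from the seed."""
    rng = np.random.default_rng(cfg.seed)
    known_ts, novel_ts, sizes, gaps = _layout_genome(cfg, rng)
    known = Annotation(
        [GeneModel(t.id, [t]) for t in known_ts], sizes
    )
    tissues = list(cfg.tissues)
    sample_names = [f"sample_{i:02d}" for i in range(cfg.n_samples)]
    sample_tissue = {
        name: tissues[i % len(tissues)] for i, name in enumerate(sample_names)
    }

    # --- expression ground truth (per transcript per tissue, then samples)
    lo, hi = cfg.fpkm_log2_range
    known_fpkm: dict[str, dict[str, float]] = {}
    for t in known_ts:
        known_fpkm[t.id] = {
            tis: 0.0 if rng.random() < cfg.known_silent_prob
            else float(2 ** rng.uniform(lo, hi))
            for tis in tissues
        }
    tissues_of: dict[str, set[str]] = {}
    novel_fpkm: dict[str, dict[str, float]] = {}
    for t in novel_ts:
        active = {tis for tis in tissues if rng.random() < 0.6}
        if not active:
            active = {tissues[int(rng.integers(0, len(tissues)))]}
        tissues_of[t.id] = active
        novel_fpkm[t.id] = {
            tis: float(2 ** rng.uniform(lo, hi)) if tis in active else 0.0
            for tis in tissues
        }
    all_fpkm = {**known_fpkm, **novel_fpkm}
    expr_df = pd.DataFrame(
        {
            name: [all_fpkm[tid][sample_tissue[name]] for tid in all_fpkm]
            for name in sample_names
        },
        index=list(all_fpkm),
    )
    expression = ExpressionMatrix(expr_df)

    # --- per-sample assemblies: known fragments + surviving novels
    assemblies: list[list[TranscriptModel]] = []
    for name in sample_names:
        models: list[TranscriptModel] = []
        k = 0
        for t in known_ts:
            if rng.random() < cfg.fragment_prob:
                frag = _fragment(t, rng, f"{name}_t{k:05d}")
                frag.source_samples = {name}
                models.append(frag)
                k += 1
        for t in novel_ts:
            if rng.random() >= cfg.dropout:
                exons = _jitter_exons(t.exons, cfg.jitter_sd, rng)
                exons = [
                    GenomicInterval(e.chrom, e.start, e.end, UNKNOWN)
                    for e in exons
                ]
                nt = TranscriptModel(
                    f"{name}_t{k:05d}", t.chrom, UNKNOWN, exons,
                    source_samples={name},
                )
                models.append(nt)
                k += 1
        assemblies.append(models)

    # --- peaks per tissue (planted + decoys)
    truth_peaks: dict[str, PeakSet] = {}
    peaksets: dict[str, PeakSet] = {}
    for tis in tissues:
        planted = []
        for t in known_ts:
            if known_fpkm[t.id][tis] > 0:
                planted.append(_plant_peak(t, cfg, known_fpkm[t.id][tis]))
        for t in novel_ts:
            if tis in tissues_of[t.id]:
                planted.append(_plant_peak(t, cfg, novel_fpkm[t.id][tis]))
        truth_peaks[tis] = PeakSet(list(planted), tis)
        decoys = []
        n_decoys = int(round(cfg.decoy_fraction * len(planted)))
        flat_gaps = [
            (chrom, s, e)
            for chrom, chrom_gaps in sorted(gaps.items())
            for s, e in chrom_gaps
            if e - s > cfg.peak_width + 5000
        ]
        for _ in range(n_decoys):
            chrom, s, e = flat_gaps[int(rng.integers(0, len(flat_gaps)))]
            pos = int(rng.integers(s + 2500, e - 2500 - cfg.peak_width))
            decoys.append(
                Peak(
                    GenomicInterval(chrom, pos, pos + cfg.peak_width),
                    1.0,
                    pos + cfg.peak_width // 2,
                )
            )
        peaksets[tis] = PeakSet(planted + decoys, tis)

    # --- coverage per tissue: 5'-weighted kernel scaled by FPKM
    tracks = {
        tis: _coverage_track(
            known_ts + novel_ts,
            {tid: all_fpkm[tid][tis] for tid in all_fpkm},
            sizes,
            cfg,
        )
        for tis in tissues
    }

    truth = TruthSet(novel_ts, tissues_of, truth_peaks, expression)
    return Fixture(
        cfg, known, assemblies, sample_names, peaksets, tracks, expression, truth
    )


def _coverage_track(
    transcripts: Sequence[TranscriptModel],
    fpkm: dict[str, float],
    sizes: dict[str, int],
    cfg: SynthConfig,
) -> CoverageTrack:
    """Sum per-transcript kernels into a binned stepwise track.

    Each expressed transcript contributes a flat bump of height FPKM over
    [TSS-offset-ish flank) and a linear 5'-to-3' decay from FPKM to 0
    along its span, mimicking promoter-proximal H3K4me3 enrichment.
    """
    step = cfg.coverage_bin
    dense = {c: np.zeros(-(-n // step), dtype=np.float64) for c, n in sizes.items()}
    flank = cfg.peak_offset
    for t in transcripts:
        a = fpkm.get(t.id, 0.0)
        if a <= 0:
            continue
        arr = dense[t.chrom]
        span = t.span
        L = len(span)
        nb = arr.size
        # body decay, 5' -> 3'
        for b in range(span.start // step, -(-span.end // step)):
            if not 0 <= b < nb:
                continue
            mid = b * step + step / 2
            d = (mid - span.start) if t.strand != REVERSE else (span.end - mid)
            d = min(max(d, 0.0), L)
            arr[b] += a * (1.0 - d / L)
        # flat flank upstream of the TSS
        tss = _tss(t)
        if t.strand != REVERSE:
            f_lo, f_hi = tss - flank, tss
        else:
            f_lo, f_hi = tss, tss + flank
        for b in range(max(0, f_lo // step), min(nb, -(-f_hi // step))):
            arr[b] += a
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, arr in dense.items():
        chrom_runs = []
        for b, v in enumerate(arr):
            if v <= 0:
                continue
            start = b * step
            end = min((b + 1) * step, sizes[chrom])
            v = float(np.round(v, 6))
            if chrom_runs and chrom_runs[-1][1] == start and chrom_runs[-1][2] == v:
                chrom_runs[-1] = (chrom_runs[-1][0], end, v)
            else:
                chrom_runs.append((start, end, v))
        runs[chrom] = chrom_runs
    return CoverageTrack(runs)


# ---------------------------------------------------------------------------
# File emission


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, object]:
    """Write the fixture as the pipeline's on-disk inputs.

    Layout: known.gtf, chrom.sizes, assemblies/<sample>.gtf,
    peaks/<tissue>.narrowPeak, coverage/<tissue>.bedGraph,
    expression.tsv, truth.json. Deterministic: the same fixture writes
    byte-identical files.
    """
    outdir = Path(outdir)
    (outdir / "assemblies").mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)
    (outdir / "coverage").mkdir(exist_ok=True)
    write_gtf(fixture.known, outdir / "known.gtf")
    write_chrom_sizes(fixture.known.chrom_sizes, outdir / "chrom.sizes")
    assembly_paths = []
    for name, models in zip(fixture.sample_names, fixture.assemblies):
        p = outdir / "assemblies" / f"{name}.gtf"
        write_gtf(models, p)
        assembly_paths.append(str(p))
    peak_paths = {}
    for tis, ps in fixture.peaksets.items():
        p = outdir / "peaks" / f"{tis}.narrowPeak"
        write_peaks_narrowpeak(ps, p)
        peak_paths[tis] = str(p)
    track_paths = {}
    for tis, track in fixture.tracks.items():
        p = outdir / "coverage" / f"{tis}.bedGraph"
        write_bedgraph(track, p)
        track_paths[tis] = str(p)
    write_expression(fixture.expression, outdir / "expression.tsv")
    truth_obj = {
        t.id: {
            "chrom": t.chrom,
            "start": t.span.start,
            "end": t.span.end,
            "strand": t.strand,
            "exons": [[e.start, e.end] for e in t.exons],
            "tissues": sorted(fixture.truth.tissues_of[t.id]),
        }
        for t in fixture.truth.novels
    }
    (outdir / "truth.json").write_text(json.dumps(truth_obj, indent=1, sort_keys=True))
    manifest = {
        "known_gtf": str(outdir / "known.gtf"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
        "assemblies": assembly_paths,
        "peaks": peak_paths,
        "coverage": track_paths,
        "expression": str(outdir / "expression.tsv"),
        "truth": str(outdir / "truth.json"),
    }

    def _rel(v):
        if isinstance(v, str):
            return str(Path(v).relative_to(outdir))
        if isinstance(v, list):
            return [_rel(x) for x in v]
        return {k: _rel(x) for k, x in v.items()}

    # the on-disk manifest uses relative paths so the directory is relocatable
    (outdir / "manifest.json").write_text(
        json.dumps({k: _rel(v) for k, v in manifest.items()}, indent=1, sort_keys=True)
    )
    return manifest


def load_truth(path: str | Path) -> tuple[list[TranscriptModel], dict[str, set[str]]]:
    """Read truth.json back into transcript models and tissue patterns."""
    obj = json.loads(Path(path).read_text())
    novels, tissues_of = [], {}
    for tid, rec in sorted(obj.items()):
        strand = rec["strand"]
        exons = [
            GenomicInterval(rec["chrom"], s, e, strand) for s, e in rec["exons"]
        ]
        novels.append(TranscriptModel(tid, rec["chrom"], strand, exons))
        tissues_of[tid] = set(rec["tissues"])
    return novels, tissues_of


# ---------------------------------------------------------------------------
# Truth-based evaluation


@dataclass
class RecoveryReport:
    precision: float
    recall: float
    strand_accuracy: float
    n_predicted: int
    n_truth: int
    n_matched_truth: int
    precision_by_convention: bool
    specificity_confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    def as_dict(self) -> dict[str, object]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "strand_accuracy": self.strand_accuracy,
            "n_predicted": self.n_predicted,
            "n_truth": self.n_truth,
            "n_matched_truth": self.n_matched_truth,
            "precision_by_convention": self.precision_by_convention,
        }


def evaluate_recovery(
    predicted: Sequence[TranscriptModel],
    truth_novels: Sequence[TranscriptModel],
    min_match_fraction: float = 0.5,
    predicted_tissues: Optional[dict[str, set[str]]] = None,
    truth_tissues: Optional[dict[str, set[str]]] = None,
    n_tissues: int = 3,
) -> RecoveryReport:
    """Score predicted novels against the planted truth.

    A prediction matches a truth transcript when their exonic overlap is
    at least ``min_match_fraction`` of the shorter one's exonic length.
    Precision over predictions, recall over truth; strand accuracy over
    matched pairs whose truth strand is known (an unknown predicted
    strand counts as wrong). With no predictions, precision is reported
    as 1.0 by convention with ``precision_by_convention`` set.
    """
    from .intervals import exonic_overlap_bp  # local to avoid cycle noise

    def matches(p: TranscriptModel, t: TranscriptModel) -> bool:
        ov = exonic_overlap_bp(p, t)
        shorter = min(p.exonic_length, t.exonic_length)
        return shorter > 0 and ov >= min_match_fraction * shorter

    match_of: dict[str, TranscriptModel] = {}
    matched_truth: set[str] = set()
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in truth_novels:
        by_chrom.setdefault(t.chrom, []).append(t)
    for p in predicted:
        cands = [t for t in by_chrom.get(p.chrom, []) if matches(p, t)]
        if cands:
            best = max(cands, key=lambda t: exonic_overlap_bp(p, t))
            match_of[p.id] = best
            matched_truth.add(best.id)

    n_pred = len(predicted)
    n_truth = len(truth_novels)
    if n_pred == 0:
        precision, by_conv = 1.0, True
    else:
        precision, by_conv = len(match_of) / n_pred, False
    recall = len(matched_truth) / n_truth if n_truth else 1.0

    strand_pairs = [
        (p, match_of[p.id]) for p in predicted
        if p.id in match_of and match_of[p.id].strand != UNKNOWN
    ]
    if strand_pairs:
        correct = sum(1 for p, t in strand_pairs if p.strand == t.strand)
        strand_acc = correct / len(strand_pairs)
    else:
        strand_acc = 1.0

    confusion: dict[tuple[str, str], int] = {}
    if predicted_tissues is not None and truth_tissues is not None:
        def label(tis: set[str]) -> str:
            if len(tis) == 0:
                return "none"
            if len(tis) == n_tissues:
                return "all-tissues"
            return "single-tissue" if len(tis) == 1 else "subset"

        for p in predicted:
            if p.id not in match_of:
                continue
            t = match_of[p.id]
            key = (
                label(truth_tissues.get(t.id, set())),
                label(predicted_tissues.get(p.id, set())),
            )
            confusion[key] = confusion.get(key, 0) + 1

    return RecoveryReport(
        precision=precision,
        recall=recall,
        strand_accuracy=strand_acc,
        n_predicted=n_pred,
        n_truth=n_truth,
        n_matched_truth=len(matched_truth),
        precision_by_convention=by_conv,
        specificity_confusion=confusion,
    )
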