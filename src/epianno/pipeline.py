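"""End-to-end orchestration: discover novel transcripts, then re-annotate.

A :class:`PipelineConfig` names the inputs and carries every tunable
parameter with its protocol default; ``run_discover`` executes
merge -> subtract -> peak co-occurrence -> strand -> specificity and
writes the novel GTF, the support table and a JSON run log with input
checksums and per-stage counts, so the headline numbers of a run are
reproducible from the log alone. ``run_annotate`` recomputes the region
partition and peak distributions for the known annotation or for
known-plus-novel, so before/after comparisons are a diff of two reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import discovery, epimetrics
from .intervals import Annotation, GeneModel
from .io import (
    PeakSet,
    read_chrom_sizes,
    read_expression,
    read_gtf,
    read_peaks,
    write_gtf,
)


@dataclass
class PipelineConfig:
    known_gtf: str
    chrom_sizes: str
    assembly_gtfs: list[str]
    peak_files: dict[str, str]  # tissue -> path
    peak_dialect: str = "narrowPeak"
    coverage_files: dict[str, str] = field(default_factory=dict)
    expression_tsv: Optional[str] = None
    outdir: str = "epianno_out"
    promoter_bp: int = 2000
    strand_max_center_dist: int = 2000
    log2fc_threshold: float = 0.6
    pseudocount: float = 1.0
    flank_bp: int = 1000
    body_bins: int = 100
    flank_bin_bp: int = 50
    n_quantiles: int = 9
    k_clusters: int = 6
    min_match_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("promoter_bp", "strand_max_center_dist", "flank_bp",
                     "body_bins", "flank_bin_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate_paths(self) -> None:
        paths = [self.known_gtf, self.chrom_sizes, *self.assembly_gtfs,
                 *self.peak_files.values(), *self.coverage_files.values()]
        if self.expression_tsv:
            paths.append(self.expression_tsv)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


def _md5(path: str | Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


@dataclass
class DiscoverResult:
    novel: list
    support: discovery.SupportTable
    log: dict

    @property
    def n_final(self) -> int:
        return len(self.novel)


def run_discover(config: PipelineConfig) -> DiscoverResult:
    """Run the discovery stages and write novel.gtf + support_table.tsv."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sizes = read_chrom_sizes(config.chrom_sizes)
    known = read_gtf(config.known_gtf, sizes)
    assemblies = [
        list(read_gtf(p, sizes).transcripts()) for p in config.assembly_gtfs
    ]
    peaksets = [
        read_peaks(path, config.peak_dialect, tissue)
        for tissue, path in sorted(config.peak_files.items())
    ]

    clusters = discovery.merge_assemblies(assemblies)
    merged = [c.merged for c in clusters]
    candidates = discovery.subtract_known(merged, known)
    support = discovery.peak_cooccurrence(
        candidates, peaksets, config.strand_max_center_dist
    )
    novel = discovery.final_novel_set(support)

    write_gtf(novel, outdir / "novel.gtf")
    support.write_tsv(outdir / "support_table.tsv")

    log = {
        "inputs": {
            "known_gtf": _md5(config.known_gtf),
            "assemblies": {p: _md5(p) for p in config.assembly_gtfs},
            "peaks": {t: _md5(p) for t, p in sorted(config.peak_files.items())},
        },
        "parameters": {
            "strand_max_center_dist": config.strand_max_center_dist,
            "promoter_bp": config.promoter_bp,
            "peak_dialect": config.peak_dialect,
        },
        "counts": {
            "n_input_transcripts": sum(len(a) for a in assemblies),
            "n_merged": len(merged),
            "n_candidates": len(candidates),
            "n_supported_per_tissue": {
                t: sum(1 for r in support if r.support[t])
                for t in support.tissues
            },
            "n_supported_any": sum(1 for r in support if r.supported_any),
            "n_final": len(novel),
            "specificity": {
                lbl: sum(1 for r in support if r.specificity == lbl)
                for lbl in ("all-tissues", "subset", "single-tissue", "none")
            },
        },
    }
    (outdir / "discover_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return DiscoverResult(novel, support, log)


def reannotated(known: Annotation, novel_transcripts) -> Annotation:
    """The known annotation plus the novel transcripts as single-isoform genes."""
    genes = list(known.genes) + [
        GeneModel(t.id, [t]) for t in novel_transcripts
    ]
    return Annotation(genes, known.chrom_sizes)


@dataclass
class AnnotateResult:
    variant: str
    genome_fractions: dict[str, float]
    peak_distributions: dict[str, dict[str, float]]  # tissue -> class -> pct
    associated_gene_counts: dict[str, int]


def run_annotate(config: PipelineConfig, variant: str = "known") -> AnnotateResult:
    """Region partition + peak distribution + peak-gene association report.

    ``variant="known+novel"`` requires a prior ``run_discover`` whose
    novel.gtf sits in the configured output directory.
    """
    if variant not in ("known", "known+novel"):
        raise ValueError(f"unknown annotation variant {variant!r}")
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = read_chrom_sizes(config.chrom_sizes)
    annotation = read_gtf(config.known_gtf, sizes)
    if variant == "known+novel":
        novel_path = outdir / "novel.gtf"
        if not novel_path.exists():
            raise FileNotFoundError(
                f"{novel_path} not found; run discover first"
            )
        novel = list(read_gtf(novel_path, sizes).transcripts())
        annotation = reannotated(annotation, novel)

    partition = epimetrics.build_region_partition(
        annotation, sizes, config.promoter_bp
    )
    fractions = epimetrics.region_fractions(partition)
    tag = variant.replace("+", "_")
    pd.Series(fractions).rename("percent").to_csv(
        outdir / f"region_fractions.{tag}.tsv", sep="\t", index_label="class"
    )
    peak_dists: dict[str, dict[str, float]] = {}
    assoc_counts: dict[str, int] = {}
    for tissue, path in sorted(config.peak_files.items()):
        peaks = read_peaks(path, config.peak_dialect, tissue)
        dist = epimetrics.peak_region_distribution(peaks, partition)
        peak_dists[tissue] = dist
        pd.Series(dist).rename("percent").to_csv(
            outdir / f"peak_distribution.{tissue}.{tag}.tsv",
            sep="\t", index_label="class",
        )
        assoc = epimetrics.associate_peaks_to_genes(
            peaks, annotation, config.promoter_bp
        )
        assoc_counts[tissue] = len(assoc)
        with open(outdir / f"associated_genes.{tissue}.{tag}.tsv", "w") as fh:
            fh.write("gene_id\tn_peaks\n")
            for gid in sorted(assoc):
                fh.write(f"{gid}\t{len(assoc[gid])}\n")
    summary = {
        "variant": variant,
        "genome_fractions": fractions,
        "peak_distributions": peak_dists,
        "associated_gene_counts": assoc_counts,
    }
    (outdir / f"annotate.{tag}.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    return AnnotateResult(variant, fractions, peak_dists, assoc_counts)
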