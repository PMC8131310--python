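"""Differential expression by fold-change threshold, differential-peak
gene mapping, set overlaps, and TSS-signal clustering.

Differential H3K4me3 regions themselves are an upstream input (two-sample
peak calling is outside this package); here they are mapped to genes with
the same body-plus-upstream window used for ordinary peak association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .epimetrics import associate_peaks_to_genes
from .intervals import Annotation
from .io import ExpressionMatrix, PeakSet

UP_IN_A = "up_in_A"
UP_IN_B = "up_in_B"
NOT_DE = "not_DE"


@dataclass
class DiffResult:
    """Per-transcript log2 fold changes and direction calls."""

    table: pd.DataFrame  # index transcript_id; columns log2fc, direction
    sample_a: str
    sample_b: str
    log2fc_threshold: float
    pseudocount: float

    def genes_up_in(self, side: str) -> set[str]:
        direction = UP_IN_A if side == "A" else UP_IN_B
        return set(self.table.index[self.table["direction"] == direction])

    def degs(self) -> set[str]:
        return set(self.table.index[self.table["direction"] != NOT_DE])


def differential_expression(
    expr: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
    log2fc_threshold: float = 0.6,
    pseudocount: float = 1.0,
) -> DiffResult:
    """Call differential transcripts by |log2 fold change| > threshold.

    log2FC = log2((FPKM_a + pseudocount) / (FPKM_b + pseudocount)); the
    pseudocount keeps zero-FPKM transcripts finite.
    """
    for s in (sample_a, sample_b):
        if s not in expr.samples:
            raise KeyError(f"sample {s!r} not in expression matrix")
    a = expr.df[sample_a].to_numpy() + pseudocount
    b = expr.df[sample_b].to_numpy() + pseudocount
    log2fc = np.log2(a / b)
    direction = np.where(
        np.abs(log2fc) > log2fc_threshold,
        np.where(log2fc > 0, UP_IN_A, UP_IN_B),
        NOT_DE,
    )
    table = pd.DataFrame(
        {"log2fc": log2fc, "direction": direction}, index=expr.df.index
    )
    return DiffResult(table, sample_a, sample_b, log2fc_threshold, pseudocount)


def genes_with_differential_peaks(
    diff_regions: PeakSet,
    annotation: Annotation,
    upstream_bp: int = 2000,
) -> set[str]:
    """Genes whose body-plus-upstream window overlaps a differential region."""
    return set(associate_peaks_to_genes(diff_regions, annotation, upstream_bp))


@dataclass(frozen=True)
class OverlapCounts:
    """Venn counts for two gene sets."""

    intersection: int
    only_a: int
    only_b: int
    label_a: str = "A"
    label_b: str = "B"

    @property
    def size_a(self) -> int:
        return self.intersection + self.only_a

    @property
    def size_b(self) -> int:
        return self.intersection + self.only_b


def overlap_sets(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    label_a: str = "A",
    label_b: str = "B",
) -> OverlapCounts:
    a, b = set(genes_a), set(genes_b)
    return OverlapCounts(len(a & b), len(a - b), len(b - a), label_a, label_b)


def cluster_tss_signal(
    signal: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
) -> pd.Series:
    """k-means clustering of per-gene TSS-flanking signal shapes.

    Rows are max-normalized so clusters group signal *shape* (upstream vs
    downstream vs centered enrichment) rather than amplitude. Rows with
    all-zero signal cannot be shape-normalized and are pre-assigned to a
    dedicated zero cluster labeled -1; the remaining rows are clustered
    into labels 0..k-1 with k-means++ initialization at a fixed seed, so
    the assignment is deterministic given (input, seed).
    """
    values = signal.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("signal matrix contains non-finite values")
    row_max = values.max(axis=1)
    nonzero = row_max > 0
    if k > int(nonzero.sum()):
        raise ValueError(
            f"k={k} exceeds the {int(nonzero.sum())} rows with signal"
        )
    labels = np.full(values.shape[0], -1, dtype=int)
    normed = values[nonzero] / row_max[nonzero, None]
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=1, max_iter=300,
        random_state=seed,
    )
    labels[nonzero] = km.fit_predict(normed)
    return pd.Series(labels, index=signal.index, name="cluster")


def hierarchical_order(
    expr: ExpressionMatrix,
    transform: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> tuple[list[str], np.ndarray]:
    """Average-linkage hierarchical clustering of transcript rows.

    Rows are transformed (default log2(x+1)), sorted by id for a
    deterministic tie rule, then clustered with Euclidean distance.
    Returns the dendrogram leaf order (row ids) and the linkage matrix.
    """
    if len(expr.transcripts) < 2:
        raise ValueError("need at least two rows to cluster")
    df = expr.df.sort_index()
    values = df.to_numpy(dtype=float)
    values = np.log2(values + 1.0) if transform is None else transform(values)
    z = linkage(pdist(values, metric="euclidean"), method="average")
    order = [df.index[i] for i in leaves_list(z)]
    return order, z
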