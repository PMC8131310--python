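"""Region partition, peak distribution, gene association and profiling."""

import numpy as np
import pytest

from epianno.epimetrics import (
    REGION_CLASSES,
    associate_peaks_to_genes,
    build_region_partition,
    metagene_profile,
    normalize_per_million,
    peak_region_distribution,
    profiles_by_expression_quantile,
    quantile_groups,
    region_fractions,
)
from epianno.intervals import Annotation, GeneModel, GenomicInterval
from epianno.io import CoverageTrack, ExpressionMatrix, Peak, PeakSet
import pandas as pd

from conftest import brute_force_labels, make_transcript, random_annotation


# ---------------------------------------------------------------------------
# partition


def test_worked_single_gene_partition(toy_annotation):
    part = build_region_partition(toy_annotation, promoter_bp=2000)
    assert part.class_bp() == {
        "promoter": 2000,
        "utr5": 200,
        "coding_exon": 900,
        "utr3": 500,
        "intron": 1400,
        "intergenic": 5000,
    }
    fr = region_fractions(part)
    assert fr == pytest.approx(
        {
            "promoter": 20.0, "utr5": 2.0, "coding_exon": 9.0,
            "utr3": 5.0, "intron": 14.0, "intergenic": 50.0,
        }
    )
    assert sum(fr.values()) == pytest.approx(100.0, abs=1e-9)


def test_empty_annotation_is_all_intergenic():
    ann = Annotation([], {"chr1": 5000})
    part = build_region_partition(ann)
    assert region_fractions(part) == pytest.approx(
        {cls: (100.0 if cls == "intergenic" else 0.0) for cls in REGION_CLASSES}
    )


def test_partition_matches_per_base_oracle(rng):
    """Random annotations (overlapping genes included) vs the mask oracle."""
    for _ in range(30):
        ann = random_annotation(
            rng, n_genes=int(rng.integers(0, 15)), chrom_len=30_000, n_chroms=2
        )
        part = build_region_partition(ann, promoter_bp=2000)
        oracle = brute_force_labels(ann, ann.chrom_sizes, promoter_bp=2000)
        for chrom in ann.chrom_sizes:
            got = np.array(
                [part.label_at(chrom, p) for p in range(ann.chrom_sizes[chrom])],
                dtype=object,
            )
            assert (got == oracle[chrom]).all()
        assert sum(part.class_bp().values()) == sum(ann.chrom_sizes.values())


def test_partition_runs_tile_the_chromosome(toy_annotation):
    part = build_region_partition(toy_annotation)
    runs = part.runs("chr1")
    assert runs[0][0] == 0 and runs[-1][1] == 10_000
    for (_, e1, _), (s2, _, _) in zip(runs, runs[1:]):
        assert e1 == s2
    labels = [lbl for _, _, lbl in runs]
    assert all(a != b for a, b in zip(labels, labels[1:]))  # maximal runs


def test_overlapping_promoters_counted_once():
    genes = [
        GeneModel("g1", [make_transcript("t1", "chr1", [(3000, 4000)], "+")]),
        GeneModel("g2", [make_transcript("t2", "chr1", [(3500, 4500)], "+")]),
    ]
    ann = Annotation(genes, {"chr1": 10_000})
    part = build_region_partition(ann, promoter_bp=2000)
    # promoter bases: [1000,3000) for g1 and [1500,3500) for g2, union minus genic
    assert sum(part.class_bp().values()) == 10_000
    assert part.class_bp()["promoter"] == 2000  # [1000,3000); [3000,3500) is exonic


# ---------------------------------------------------------------------------
# peak distribution


def test_peak_distribution_worked_example(toy_annotation):
    part = build_region_partition(toy_annotation)
    ps = PeakSet([Peak(GenomicInterval("chr1", 1500, 2500), 1.0, 2000)], "leaf")
    dist = peak_region_distribution(ps, part)
    assert dist["promoter"] == pytest.approx(50.0)
    assert dist["utr5"] == pytest.approx(20.0)
    assert dist["coding_exon"] == pytest.approx(30.0)
    assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)


def test_wholly_intergenic_peak(toy_annotation):
    part = build_region_partition(toy_annotation)
    ps = PeakSet([Peak(GenomicInterval("chr1", 7000, 7500), 1.0, 7250)], "leaf")
    assert peak_region_distribution(ps, part)["intergenic"] == pytest.approx(100.0)


def test_peak_distribution_matches_per_base_tally(rng):
    ann = random_annotation(rng, n_genes=8, chrom_len=30_000)
    part = build_region_partition(ann)
    oracle = brute_force_labels(ann, ann.chrom_sizes)
    peaks = []
    for _ in range(25):
        s = int(rng.integers(0, 29_000))
        peaks.append(Peak(GenomicInterval("chr1", s, s + int(rng.integers(1, 900))), 1.0, s))
    dist = peak_region_distribution(PeakSet(peaks, "x"), part)
    tally = {cls: 0 for cls in REGION_CLASSES}
    for p in peaks:
        for pos in range(p.interval.start, p.interval.end):
            tally[oracle["chr1"][pos]] += 1
    total = sum(tally.values())
    for cls in REGION_CLASSES:
        assert dist[cls] == pytest.approx(100.0 * tally[cls] / total)


def test_peak_beyond_bounds_is_clipped_with_warning(toy_annotation):
    part = build_region_partition(toy_annotation)
    ps = PeakSet([Peak(GenomicInterval("chr1", 9500, 10_500), 1.0, 9700)], "leaf")
    with pytest.warns(UserWarning, match="clipped"):
        dist = peak_region_distribution(ps, part)
    assert dist["intergenic"] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# peak-gene association


def _ann(*genes):
    return Annotation(list(genes), {"chr1": 50_000})


def test_association_upstream_window_forward():
    gene = GeneModel("g", [make_transcript("t", "chr1", [(5000, 8000)], "+")])
    ann = _ann(gene)
    hit = PeakSet([Peak(GenomicInterval("chr1", 3500, 4200), 1.0, 3850)], "x")
    miss = PeakSet([Peak(GenomicInterval("chr1", 1000, 1500), 1.0, 1250)], "x")
    assert set(associate_peaks_to_genes(hit, ann)) == {"g"}
    assert associate_peaks_to_genes(miss, ann) == {}


def test_association_upstream_window_reverse():
    gene = GeneModel("g", [make_transcript("t", "chr1", [(5000, 8000)], "-")])
    ann = _ann(gene)
    hit = PeakSet([Peak(GenomicInterval("chr1", 8100, 8400), 1.0, 8250)], "x")
    upstream_of_fwd = PeakSet([Peak(GenomicInterval("chr1", 3500, 4200), 1.0, 3850)], "x")
    assert set(associate_peaks_to_genes(hit, ann)) == {"g"}
    assert associate_peaks_to_genes(upstream_of_fwd, ann) == {}


def test_association_matches_all_pairs_scan(rng):
    ann = random_annotation(rng, n_genes=20, chrom_len=40_000)
    peaks = []
    for _ in range(40):
        s = int(rng.integers(0, 39_000))
        peaks.append(Peak(GenomicInterval("chr1", s, s + int(rng.integers(50, 800))), 1.0, s))
    ps = PeakSet(peaks, "x")
    got = associate_peaks_to_genes(ps, ann, upstream_bp=2000)
    expected = {}
    for gene in ann:
        span = gene.span
        if gene.strand == "+":
            ws, we = span.start - 2000, span.end
        else:
            ws, we = span.start, span.end + 2000
        hits = [p for p in peaks if min(p.interval.end, we) - max(p.interval.start, max(0, ws)) >= 1]
        if hits:
            expected[gene.id] = len(hits)
    assert {g: len(v) for g, v in got.items()} == expected


# ---------------------------------------------------------------------------
# normalization


def test_per_million_normalization_scales_area():
    track = CoverageTrack({"chr1": [(0, 100, 30.0), (200, 250, 12.0)]})
    normed = normalize_per_million(track, 30_000_000)
    assert normed.value_at("chr1", 50) == pytest.approx(1.0)
    assert normed.value_at("chr1", 150) == 0.0
    assert normed.total_area() == pytest.approx(track.total_area() * 1e6 / 30_000_000)
    with pytest.raises(ValueError, match="already normalized"):
        normalize_per_million(normed, 30_000_000)
    with pytest.raises(ValueError):
        normalize_per_million(track, 0)


# ---------------------------------------------------------------------------
# metagene profiles


def _gene(start, end, strand="+", gid="g"):
    return GeneModel(gid, [make_transcript(f"{gid}_t", "chr1", [(start, end)], strand)])


def test_constant_coverage_gives_constant_profile():
    track = CoverageTrack({"chr1": [(0, 50_000, 2.0)]})
    genes = [_gene(5000, 9000, "+", "a"), _gene(20_000, 20_123, "-", "b")]
    prof = metagene_profile(track, genes)
    assert prof.values == pytest.approx(np.full(140, 2.0))
    assert prof.n_genes == 2


def test_zero_coverage_gives_zero_profile():
    track = CoverageTrack({})
    prof = metagene_profile(track, [_gene(5000, 9000)])
    assert prof.values == pytest.approx(np.zeros(140))


def test_step_signal_profile_matches_per_base_means():
    """One forward gene with a step inside the body, checked bin by bin."""
    gene = _gene(2000, 4000)  # body 2000 bp -> 20 bp per body bin
    track = CoverageTrack({"chr1": [(1000, 3000, 1.0), (3000, 6000, 5.0)]})
    prof = metagene_profile(track, [gene], flank_bp=1000, body_bins=100, flank_bin_bp=50)
    dense = np.zeros(6000)
    dense[1000:3000] = 1.0
    dense[3000:6000] = 5.0
    window = dense[1000:5000]
    expected = []
    for b in range(20):
        expected.append(window[b * 50 : (b + 1) * 50].mean())
    for b in range(100):
        expected.append(window[1000 + b * 20 : 1000 + (b + 1) * 20].mean())
    for b in range(20):
        expected.append(window[3000 + b * 50 : 3000 + (b + 1) * 50].mean())
    assert prof.values == pytest.approx(np.array(expected))


def test_reverse_gene_profile_is_flipped():
    # signal only over the 5' half of a reverse gene
    track = CoverageTrack({"chr1": [(3000, 4000, 4.0)]})
    gene = _gene(2000, 4000, "-")
    prof = metagene_profile(track, [gene], flank_bp=1000, body_bins=10, flank_bin_bp=100)
    body = prof.values[10:20]
    assert body[:5] == pytest.approx(np.full(5, 4.0))  # 5'-most bins carry it
    assert body[5:] == pytest.approx(np.zeros(5))


def test_short_body_uses_fractional_bins():
    track = CoverageTrack({"chr1": [(0, 50_000, 3.0)]})
    gene = _gene(10_000, 10_007)  # 7 bp body, 100 bins
    prof = metagene_profile(track, [gene])
    assert prof.values == pytest.approx(np.full(140, 3.0))


def test_out_of_bounds_flank_reads_zero():
    track = CoverageTrack({"chr1": [(0, 5000, 2.0)]})
    gene = _gene(200, 1200)  # upstream flank extends to -800
    prof = metagene_profile(track, [gene], flank_bp=1000, body_bins=10, flank_bin_bp=100)
    assert prof.values[:8] == pytest.approx(np.zeros(8))  # before the chromosome
    assert prof.values[8] == pytest.approx(2.0)  # first in-bounds flank bin


# ---------------------------------------------------------------------------
# expression quantiles


def _expr(values: dict[str, float], sample="s1"):
    return ExpressionMatrix(pd.DataFrame({sample: pd.Series(values)}))


def test_nine_singletons_for_nine_distinct_genes():
    genes = [_gene(1000 * (i + 1) + 5000, 1000 * (i + 1) + 5400, gid=f"g{i}") for i in range(9)]
    expr = _expr({f"g{i}": float(i + 1) for i in range(9)})
    groups, silent = quantile_groups(genes, expr, "s1", n_quantiles=9)
    assert [len(g) for g in groups] == [1] * 9
    assert [g[0].id for g in groups] == [f"g{i}" for i in range(9)]  # ascending
    assert silent == []


def test_remainder_goes_to_lowest_groups():
    genes = [_gene(700 * i + 5000, 700 * i + 5200, gid=f"g{i:02d}") for i in range(20)]
    expr = _expr({f"g{i:02d}": float(i + 1) for i in range(20)})
    groups, _ = quantile_groups(genes, expr, "s1", n_quantiles=9)
    assert [len(g) for g in groups] == [3, 3, 2, 2, 2, 2, 2, 2, 2]


def test_all_silent_genes_form_not_expressed_group():
    genes = [_gene(5000, 6000, gid="a"), _gene(9000, 9500, gid="b")]
    expr = _expr({"a": 0.0, "b": 0.0})
    track = CoverageTrack({"chr1": [(0, 50_000, 1.0)]})
    profiles, silent = profiles_by_expression_quantile(track, genes, expr, "s1")
    assert all(p.is_empty for p in profiles)
    assert silent.n_genes == 2


def test_tss_signal_monotone_in_expression_rank():
    """Coverage proportional to expression -> TSS bin non-decreasing by quantile."""
    rng = np.random.default_rng(7)
    genes, runs, values = [], [], {}
    for i in range(27):
        start = 4000 + i * 1500
        genes.append(_gene(start, start + 800, gid=f"g{i:02d}"))
        fpkm = float(2 ** rng.uniform(0, 8))
        values[f"g{i:02d}"] = fpkm
        runs.append((start - 500, start + 500, fpkm))
    track = CoverageTrack({"chr1": [(s, e, v) for s, e, v in sorted(runs)]})
    expr = _expr(values)
    ann_genes = genes
    profiles, _ = profiles_by_expression_quantile(track, ann_genes, expr, "s1")
    tss = [p.tss_bin_value() for p in profiles]
    assert all(a <= b + 1e-9 for a, b in zip(tss, tss[1:]))
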