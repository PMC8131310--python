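"""Merging, novelty subtraction, peak co-occurrence and strand inference."""

import numpy as np
import pytest

from epianno.discovery import (
    assign_strand,
    final_novel_set,
    merge_assemblies,
    peak_cooccurrence,
    subtract_known,
)
from epianno.intervals import (
    Annotation,
    GeneModel,
    GenomicInterval,
    exonic_overlap_bp,
)
from epianno.io import Peak, PeakSet
from conftest import make_transcript, random_transcript


def _peak(chrom, start, end, center=None):
    center = (start + end) // 2 if center is None else center
    return Peak(GenomicInterval(chrom, start, end), 1.0, center)


# ---------------------------------------------------------------------------
# merge_assemblies


def test_merge_fuses_overlapping_transcripts_across_samples():
    s1 = [make_transcript("a", "chr1", [(100, 300), (500, 700)])]
    s2 = [make_transcript("b", "chr1", [(250, 350)])]
    clusters = merge_assemblies([s1, s2])
    assert len(clusters) == 1
    assert [(e.start, e.end) for e in clusters[0].merged.exons] == [
        (100, 350), (500, 700),
    ]
    assert clusters[0].member_ids == ["a", "b"]


def test_merge_is_idempotent_and_keeps_disjoint_apart():
    s = [
        make_transcript("a", "chr1", [(100, 200)]),
        make_transcript("b", "chr1", [(300, 400)]),
    ]
    once = merge_assemblies([s])
    assert len(once) == 2
    twice = merge_assemblies([[c.merged for c in once]])
    assert [
        [(e.start, e.end) for e in c.merged.exons] for c in twice
    ] == [
        [(e.start, e.end) for e in c.merged.exons] for c in once
    ]


def test_merge_respects_strand_incompatibility():
    fwd = make_transcript("f", "chr1", [(100, 300)], strand="+")
    rev = make_transcript("r", "chr1", [(200, 400)], strand="-")
    clusters = merge_assemblies([[fwd, rev]])
    assert len(clusters) == 2
    # an unknown-strand transcript bridges to the compatible side
    unk = make_transcript("u", "chr1", [(150, 250)])
    clusters = merge_assemblies([[fwd, unk]])
    assert len(clusters) == 1
    assert clusters[0].merged.strand == "+"


def test_merge_splits_mixed_strand_component():
    """An unknown bridge between opposite strands does not fuse them."""
    fwd = make_transcript("f", "chr1", [(100, 300)], strand="+")
    bridge = make_transcript("u", "chr1", [(150, 550)])  # 150 bp with +, 50 with -
    rev = make_transcript("r", "chr1", [(500, 700)], strand="-")
    clusters = merge_assemblies([[fwd, bridge, rev]])
    groups = {tuple(c.member_ids): c.merged.strand for c in clusters}
    assert groups == {("f", "u"): "+", ("r",): "-"}
    # a perfectly tied bridge stays in its own strandless cluster
    tied = make_transcript("u", "chr1", [(250, 550)])  # 50 bp with each side
    clusters = merge_assemblies([[fwd, tied, rev]])
    groups = {tuple(c.member_ids): c.merged.strand for c in clusters}
    assert groups == {("f",): "+", ("u",): ".", ("r",): "-"}


def test_merge_order_invariance(rng):
    assemblies = [
        [random_transcript(rng, f"s{k}t{i}", max_pos=20_000) for i in range(30)]
        for k in range(4)
    ]
    ref = merge_assemblies(assemblies)
    perm = merge_assemblies(assemblies[::-1])
    key = lambda cs: [
        (c.merged.chrom, [(e.start, e.end) for e in c.merged.exons], c.member_ids)
        for c in cs
    ]
    assert key(ref) == key(perm)


def test_merge_matches_bruteforce_union_find(rng):
    """100 random instances vs an all-pairs transitive-closure oracle."""
    for trial in range(100):
        n = int(rng.integers(2, 40))
        ts = [
            random_transcript(rng, f"t{i}", max_pos=8000, strand=".")
            for i in range(n)
        ]
        clusters = merge_assemblies([ts])
        # oracle: repeated all-pairs closure over exonic overlap
        groups = [{t.id} for t in ts]
        by_id = {t.id: t for t in ts}
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    if any(
                        exonic_overlap_bp(by_id[a], by_id[b]) >= 1
                        for a in groups[i]
                        for b in groups[j]
                    ):
                        groups[i] |= groups[j]
                        del groups[j]
                        changed = True
                        break
                if changed:
                    break
        expected = sorted(tuple(sorted(g)) for g in groups)
        got = sorted(tuple(c.member_ids) for c in clusters)
        assert got == expected, f"trial {trial}"


def test_merged_exons_are_member_union(rng):
    ts = [random_transcript(rng, f"t{i}", max_pos=5000, strand=".") for i in range(20)]
    for c in merge_assemblies([ts]):
        member_bases = set()
        by_id = {t.id: t for t in ts}
        for mid in c.member_ids:
            for e in by_id[mid].exons:
                member_bases |= set(range(e.start, e.end))
        merged_bases = set()
        for e in c.merged.exons:
            merged_bases |= set(range(e.start, e.end))
        # union plus fused 0-bp adjacencies
        assert member_bases <= merged_bases
        assert merged_bases - member_bases == set()


# ---------------------------------------------------------------------------
# subtract_known


def _known(*transcripts):
    genes = [GeneModel(t.id, [t]) for t in transcripts]
    return Annotation(genes, {"chr1": 100_000})


def test_subtract_removes_exonic_overlap_keeps_adjacent():
    known = _known(make_transcript("k1", "chr1", [(1000, 2000)], "+"))
    inside = make_transcript("c1", "chr1", [(1500, 1600)])
    adjacent = make_transcript("c2", "chr1", [(2000, 2500)])
    out = subtract_known([inside, adjacent], known)
    assert [(t.id, flag) for t, flag in out] == [("c2", "intergenic")]


def test_subtract_flags_intronic_candidates():
    known = _known(
        make_transcript("k1", "chr1", [(1000, 2600), (4000, 5000)], "+")
    )
    intronic = make_transcript("c1", "chr1", [(2800, 3200)])
    outside = make_transcript("c2", "chr1", [(8000, 8500)])
    flags = dict((t.id, flag) for t, flag in subtract_known([intronic, outside], known))
    assert flags == {"c1": "intronic", "c2": "intergenic"}


def test_self_subtraction_removes_everything(rng):
    ts = [
        random_transcript(rng, f"t{i}", max_pos=50_000, strand="+")
        for i in range(40)
    ]
    known = Annotation([GeneModel(t.id, [t]) for t in ts], {"chr1": 100_000})
    assert subtract_known(list(known.transcripts()), known) == []


# ---------------------------------------------------------------------------
# peak co-occurrence


def _support_one(candidate, peaks, tissue="leaf", max_center_dist=2000):
    table = peak_cooccurrence(
        [(candidate, "intergenic")], [PeakSet(peaks, tissue)], max_center_dist
    )
    return table.records[0]


def test_span_overlap_supports():
    cand = make_transcript("c", "chr1", [(10_000, 12_000)])
    rec = _support_one(cand, [_peak("chr1", 11_000, 11_500)])
    assert rec.support["leaf"]


def test_center_within_2kb_supports():
    cand = make_transcript("c", "chr1", [(10_000, 12_000)])
    rec = _support_one(cand, [_peak("chr1", 8500, 9200, center=8850)])
    assert rec.support["leaf"]  # 1150 bp from the left end


def test_center_beyond_2kb_does_not_support():
    cand = make_transcript("c", "chr1", [(10_000, 12_000)])
    rec = _support_one(cand, [_peak("chr1", 14_500, 15_000, center=14_750)])
    assert not rec.support["leaf"]  # 2750 bp away


def test_duplicate_tissue_labels_rejected():
    cand = make_transcript("c", "chr1", [(10_000, 12_000)])
    with pytest.raises(ValueError, match="duplicate"):
        peak_cooccurrence(
            [(cand, "intergenic")],
            [PeakSet([], "leaf"), PeakSet([], "leaf")],
        )


# ---------------------------------------------------------------------------
# strand inference


@pytest.mark.parametrize(
    "center, expected",
    [
        (9500, "+"),    # 500 bp from the left end -> forward
        (12_400, "-"),  # 400 bp from the right end -> reverse
        (11_000, "."),  # 1000 bp from each end -> tie -> unknown
        (15_000, "."),  # beyond the 2 kb threshold -> no call
    ],
)
def test_assign_strand_rule(center, expected):
    cand = make_transcript("c", "chr1", [(10_000, 12_000)])
    peak = _peak("chr1", center - 300, center + 300, center=center)
    assert assign_strand(cand, [peak]) == expected


def test_assign_strand_threshold_is_strict():
    cand = make_transcript("c", "chr1", [(10_000, 12_000)])
    at = _peak("chr1", 7800, 8200, center=8000)       # exactly 2000 away
    within = _peak("chr1", 7801, 8201, center=8001)   # 1999 away
    assert assign_strand(cand, [at]) == "."
    assert assign_strand(cand, [within]) == "+"


def test_assign_strand_nearest_peak_wins_and_ties_are_unknown():
    cand = make_transcript("c", "chr1", [(10_000, 12_000)])
    near_left = _peak("chr1", 9300, 9700, center=9500)     # 500 from left
    far_right = _peak("chr1", 12_800, 13_200, center=13_000)  # 1000 from right
    assert assign_strand(cand, [near_left, far_right]) == "+"
    tied_right = _peak("chr1", 12_300, 12_700, center=12_500)  # 500 from right
    assert assign_strand(cand, [near_left, tied_right]) == "."


def test_consensus_conflict_across_tissues_is_unknown():
    cand = make_transcript("c", "chr1", [(10_000, 12_000)])
    leaf = PeakSet([_peak("chr1", 9300, 9700, center=9500)], "leaf")
    stem = PeakSet([_peak("chr1", 12_300, 12_700, center=12_500)], "stem")
    table = peak_cooccurrence([(cand, "intergenic")], [leaf, stem])
    rec = table.records[0]
    assert rec.strand_by_tissue == {"leaf": "+", "stem": "-"}
    assert rec.consensus_strand == "."


# ---------------------------------------------------------------------------
# specificity labels + final set


def test_specificity_labels_and_final_set():
    cands = [
        (make_transcript(f"c{i}", "chr1", [(s, s + 1000)]), "intergenic")
        for i, s in enumerate([10_000, 20_000, 30_000, 40_000])
    ]
    def peaks_for(starts, tissue):
        return PeakSet([_peak("chr1", s + 200, s + 800) for s in starts], tissue)
    table = peak_cooccurrence(
        cands,
        [
            peaks_for([10_000, 20_000, 30_000], "leaf"),
            peaks_for([10_000, 20_000], "stem"),
            peaks_for([10_000], "root"),
        ],
    )
    labels = {r.transcript.id: r.specificity for r in table}
    assert labels == {
        "c0": "all-tissues",
        "c1": "subset",
        "c2": "single-tissue",
        "c3": "none",
    }
    final = final_novel_set(table)
    assert {t.id for t in final} == {"c0", "c1", "c2"}  # unsupported dropped
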