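"""Novel-transcript discovery: merge multi-sample assemblies, subtract the
known annotation, keep candidates co-occurring with H3K4me3 peaks, and
infer strand from peak-center position.

The strand rule reflects how H3K4me3 marks active promoters: the mark
piles up just upstream of the TSS, so a peak center close to the left
(smaller-coordinate) end of an unstranded transcript implies the TSS is on
the left and the transcript runs forward; a center close to the right end
implies a reverse-strand transcript. "Close" means a center-to-end
distance strictly below ``max_center_dist`` (default 2000 bp).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .intervals import (
    FORWARD,
    REVERSE,
    UNKNOWN,
    Annotation,
    GenomicInterval,
    TranscriptModel,
    exonic_overlap_bp,
)
from .io import PeakSet


# ---------------------------------------------------------------------------
# Merging


@dataclass
class MergeCluster:
    """A connected group of overlapping transcripts and its merged model."""

    member_ids: list[str]
    merged: TranscriptModel


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _strands_compatible(a: str, b: str) -> bool:
    return a == UNKNOWN or b == UNKNOWN or a == b


def _coalesce(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; overlapping or exactly adjacent pieces fuse."""
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _overlapping_pairs(
    transcripts: Sequence[TranscriptModel],
) -> Iterable[tuple[int, int]]:
    """Index pairs with >=1 bp exonic overlap, found by a sweep over exons."""
    events = []  # (chrom, start, end, transcript index)
    for idx, t in enumerate(transcripts):
        for ex in t.exons:
            events.append((t.chrom, ex.start, ex.end, idx))
    events.sort()
    active: list[tuple[int, int]] = []  # (end, idx) on the current chromosome
    cur_chrom = None
    for chrom, start, end, idx in events:
        if chrom != cur_chrom:
            active = []
            cur_chrom = chrom
        active = [(e, i) for e, i in active if e > start]
        for _, other in active:
            if other != idx:
                yield (min(idx, other), max(idx, other))
        active.append((end, idx))


def _merge_members(
    members: list[TranscriptModel], cluster_id: str
) -> TranscriptModel:
    exons = _coalesce([(ex.start, ex.end) for t in members for ex in t.exons])
    known = {t.strand for t in members} - {UNKNOWN}
    strand = next(iter(known)) if len(known) == 1 else UNKNOWN
    chrom = members[0].chrom
    samples: set[str] = set()
    for t in members:
        samples |= t.source_samples
    return TranscriptModel(
        cluster_id,
        chrom,
        strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        source_samples=samples,
    )


def merge_assemblies(
    assemblies: Sequence[Sequence[TranscriptModel]],
) -> list[MergeCluster]:
    """Single-linkage merge of per-sample transcript assemblies.

    Two transcripts link when they sit on the same chromosome, their exons
    overlap by at least one base, and their strands are compatible
    (unknown is compatible with anything). Each connected component is
    fused into one transcript whose exons are the coalesced union of the
    members' exons. A component whose known strands conflict (joined
    through unknown-strand bridges) is split by strand before the union:
    forward and reverse members seed separate subclusters and each
    unknown-strand member joins the side it shares more exonic overlap
    with (ties and no-overlap go to a strandless subcluster).

    The result is deterministic and sorted by (chrom, start, id); it does
    not depend on the order of the input assemblies.
    """
    transcripts: list[TranscriptModel] = [
        t for assembly in assemblies for t in assembly
    ]
    # canonical order makes the clustering independent of input order
    transcripts.sort(key=lambda t: (t.chrom, t.span.start, t.span.end, t.id))
    if not transcripts:
        return []
    dsu = _DisjointSet(len(transcripts))
    for i, j in _overlapping_pairs(transcripts):
        if _strands_compatible(transcripts[i].strand, transcripts[j].strand):
            dsu.union(i, j)

    components: dict[int, list[int]] = {}
    for idx in range(len(transcripts)):
        components.setdefault(dsu.find(idx), []).append(idx)

    groups: list[list[TranscriptModel]] = []
    for indices in components.values():
        members = [transcripts[i] for i in indices]
        strands = {t.strand for t in members} - {UNKNOWN}
        if len(strands) <= 1:
            groups.append(members)
            continue
        # mixed-strand component: split before union
        fwd = [t for t in members if t.strand == FORWARD]
        rev = [t for t in members if t.strand == REVERSE]
        none: list[TranscriptModel] = []
        for t in members:
            if t.strand != UNKNOWN:
                continue
            ov_f = sum(exonic_overlap_bp(t, o) for o in fwd)
            ov_r = sum(exonic_overlap_bp(t, o) for o in rev)
            if ov_f > ov_r:
                fwd.append(t)
            elif ov_r > ov_f:
                rev.append(t)
            else:
                none.append(t)
        for side in (fwd, rev, none):
            if side:
                groups.append(side)

    groups.sort(key=lambda ms: (ms[0].chrom, min(t.span.start for t in ms)))
    clusters = []
    for k, members in enumerate(groups):
        merged = _merge_members(members, f"MERGE_{k:06d}")
        clusters.append(
            MergeCluster(sorted(t.id for t in members), merged)
        )
    clusters.sort(key=lambda c: (c.merged.chrom, c.merged.span.start, c.merged.id))
    for k, c in enumerate(clusters):
        c.merged.id = f"MERGE_{k:06d}"
    return clusters


# ---------------------------------------------------------------------------
# Novelty subtraction


def subtract_known(
    merged: Iterable[TranscriptModel], known: Annotation
) -> list[tuple[TranscriptModel, str]]:
    """Candidates with zero exonic overlap against every known transcript.

    Returns (transcript, location_flag) pairs; the flag is ``"intronic"``
    when the candidate span falls entirely inside one intron of a known
    transcript, else ``"intergenic"``.
    """
    out = []
    for t in merged:
        span = t.span
        hit_ids = known.query_overlapping(span)
        overlapping = [
            kt
            for gid in hit_ids
            for kt in known.gene(gid).transcripts
        ]
        if any(exonic_overlap_bp(t, kt) > 0 for kt in overlapping):
            continue
        flag = "intergenic"
        for kt in overlapping:
            for intron in kt.introns():
                if intron.start <= span.start and span.end <= intron.end:
                    flag = "intronic"
                    break
            if flag == "intronic":
                break
        out.append((t, flag))
    return out


# ---------------------------------------------------------------------------
# Peak co-occurrence and strand inference


def _end_distance(center: int, span: GenomicInterval) -> tuple[int, int]:
    """(distance to left end, distance to right end) of the span."""
    return abs(center - span.start), abs(center - span.end)


def _supported_by(peak_center: int, peak: GenomicInterval,
                  span: GenomicInterval, max_center_dist: int) -> bool:
    if peak.chrom != span.chrom:
        return False
    if min(peak.end, span.end) - max(peak.start, span.start) >= 1:
        return True
    dl, dr = _end_distance(peak_center, span)
    return min(dl, dr) < max_center_dist


def assign_strand(
    candidate: TranscriptModel,
    peaks: Iterable,
    max_center_dist: int = 2000,
) -> str:
    """Infer strand from the H3K4me3 peak center nearest a span end.

    Among peaks whose center lies strictly within ``max_center_dist`` of
    either span end, the peak with the smallest center-to-end distance
    decides: strictly nearer the left end means forward, strictly nearer
    the right end means reverse. An equidistant center, no qualifying
    peak, or a tie between peaks implying opposite strands all yield
    unknown — orientation is never fabricated.
    """
    span = candidate.span
    best_dist: Optional[int] = None
    best_calls: set[str] = set()
    for p in peaks:
        if p.interval.chrom != span.chrom:
            continue
        dl, dr = _end_distance(p.center, span)
        d = min(dl, dr)
        if d >= max_center_dist:
            continue
        call = FORWARD if dl < dr else REVERSE if dr < dl else UNKNOWN
        if best_dist is None or d < best_dist:
            best_dist, best_calls = d, {call}
        elif d == best_dist:
            best_calls.add(call)
    if best_dist is None:
        return UNKNOWN
    if best_calls == {FORWARD}:
        return FORWARD
    if best_calls == {REVERSE}:
        return REVERSE
    return UNKNOWN


def _consensus(calls: Iterable[str]) -> str:
    known = set(calls) - {UNKNOWN}
    if len(known) == 1:
        return next(iter(known))
    return UNKNOWN


@dataclass
class SupportRecord:
    transcript: TranscriptModel
    location_flag: str
    support: dict[str, bool]
    strand_by_tissue: dict[str, str]
    consensus_strand: str
    specificity: str = "none"

    @property
    def supported_any(self) -> bool:
        return any(self.support.values())

    @property
    def supporting_tissues(self) -> list[str]:
        return sorted(t for t, flag in self.support.items() if flag)


class SupportTable:
    """Per-candidate, per-tissue H3K4me3 support with inferred strands."""

    def __init__(self, records: list[SupportRecord], tissues: list[str]):
        self.records = records
        self.tissues = tissues

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def supported(self) -> list[SupportRecord]:
        return [r for r in self.records if r.supported_any]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            t = r.transcript
            row = {
                "transcript_id": t.id,
                "chrom": t.chrom,
                "start": t.span.start,
                "end": t.span.end,
                "exon_count": t.exon_count,
                "length": t.transcript_length,
                "location": r.location_flag,
            }
            for tissue in self.tissues:
                row[f"support_{tissue}"] = r.support[tissue]
                row[f"strand_{tissue}"] = r.strand_by_tissue[tissue]
            row["strand"] = r.consensus_strand
            row["specificity"] = r.specificity
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def peak_cooccurrence(
    candidates: Sequence[tuple[TranscriptModel, str]],
    peaksets: Sequence[PeakSet],
    max_center_dist: int = 2000,
) -> SupportTable:
    """Score each candidate against each tissue's peaks independently.

    A candidate is supported in a tissue when some peak either overlaps
    the candidate span by >=1 bp or has its center strictly within
    ``max_center_dist`` of either span end. For each supporting tissue a
    strand is inferred from that tissue's qualifying peaks; the consensus
    is the unique known tissue-level call, or unknown on conflict.
    """
    labels = [ps.tissue_label for ps in peaksets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate tissue labels: {labels}")
    by_chrom: dict[str, dict[str, list]] = {}
    for ps in peaksets:
        chrom_map = by_chrom.setdefault(ps.tissue_label, {})
        for p in ps:
            chrom_map.setdefault(p.interval.chrom, []).append(p)

    records = []
    for candidate, flag in candidates:
        span = candidate.span
        support: dict[str, bool] = {}
        strand_by_tissue: dict[str, str] = {}
        for tissue in labels:
            chrom_peaks = by_chrom[tissue].get(span.chrom, [])
            nearby = [
                p
                for p in chrom_peaks
                if _supported_by(p.center, p.interval, span, max_center_dist)
            ]
            support[tissue] = bool(nearby)
            if nearby:
                strand_by_tissue[tissue] = assign_strand(
                    candidate, nearby, max_center_dist
                )
            else:
                strand_by_tissue[tissue] = UNKNOWN
        records.append(
            SupportRecord(
                transcript=candidate,
                location_flag=flag,
                support=support,
                strand_by_tissue=strand_by_tissue,
                consensus_strand=_consensus(strand_by_tissue.values()),
            )
        )
    return label_tissue_specificity(SupportTable(records, labels))


def label_tissue_specificity(table: SupportTable) -> SupportTable:
    """Label each candidate all-tissues / subset / single-tissue / none."""
    n = len(table.tissues)
    for r in table.records:
        k = sum(r.support.values())
        if k == 0:
            r.specificity = "none"
        elif k == n:
            r.specificity = "all-tissues"
        elif k == 1:
            r.specificity = "single-tissue"
        else:
            r.specificity = "subset"
    return table


def final_novel_set(table: SupportTable) -> list[TranscriptModel]:
    """Supported candidates with the consensus strand stamped on.

    These are the transcripts the reannotated genome gains.
    """
    out = []
    for r in table.supported():
        t = r.transcript
        strand = r.consensus_strand
        out.append(
            TranscriptModel(
                t.id,
                t.chrom,
                strand,
                [
                    GenomicInterval(t.chrom, ex.start, ex.end, strand)
                    for ex in t.exons
                ],
                source_samples=set(r.supporting_tissues),
            )
        )
    return out
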