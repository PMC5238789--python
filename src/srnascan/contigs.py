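"""Contig assembly from mapped reads.

Every alignment record (including each placement of a multimapped read)
becomes one strand-specific genomic interval.  Per sample, intervals are
merged single-linkage wherever they overlap by at least ``contig_overlap``
bases (bookended intervals do not merge), and merged intervals supported by
fewer than ``min_contig_reads`` alignments are discarded.  Per condition, the
base-wise intersection of contig-covered positions across all samples yields
consensus contigs: the longest interval present in every sample of the
condition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .aligner import AlignmentRecord
from .config import PipelineConfig

__all__ = [
    "GenomicInterval",
    "Contig",
    "ConsensusContig",
    "alignments_to_intervals",
    "merge_contigs",
    "condition_consensus",
    "unify_consensus",
    "write_contigs_bed",
    "write_bedgraph",
    "write_consensus_tsv",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    ref_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval {self.ref_id}:{self.start}-{self.end}: start >= end")
        if self.strand not in "+-":
            raise ValueError(f"interval strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bases; 0 for different references or strands."""
        if self.ref_id != other.ref_id or self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Contig:
    """A merged, read-supported interval in one sample."""

    interval: GenomicInterval
    read_ids: list[str]  # multiset: one entry per supporting alignment
    sample_id: str

    @property
    def read_count(self) -> int:
        return len(self.read_ids)


@dataclass
class ConsensusContig:
    """A contig interval present in every sample of a condition."""

    interval: GenomicInterval
    condition: str
    per_sample_read_counts: dict[str, int] = field(default_factory=dict)

    @property
    def read_count(self) -> int:
        return sum(self.per_sample_read_counts.values())

    def key(self) -> tuple:
        iv = self.interval
        return (iv.ref_id, iv.start, iv.end, iv.strand)


def alignments_to_intervals(
    alignments: list[AlignmentRecord],
) -> list[tuple[GenomicInterval, str]]:
    """One (interval, read_id) pair per alignment record.

    A read with ``n_hits = k`` contributes k intervals, so multimapped hits
    are counted at every genomic placement.
    """
    return [
        (GenomicInterval(a.ref_id, a.start, a.end, a.strand), a.read_id)
        for a in alignments
    ]


def merge_contigs(
    intervals_with_reads: list[tuple[GenomicInterval, str]],
    sample_id: str,
    config: PipelineConfig | None = None,
) -> list[Contig]:
    """Single-linkage merge of one sample's intervals into contigs.

    Two intervals link when they overlap by at least ``contig_overlap`` bases
    on the same reference and strand; abutting intervals never merge.  Merged
    components supported by fewer than ``min_contig_reads`` alignments are
    dropped.  Output is sorted by (ref, strand, start).
    """
    cfg = config or PipelineConfig()
    by_group: dict[tuple[str, str], list[tuple[GenomicInterval, str]]] = {}
    for iv, rid in intervals_with_reads:
        by_group.setdefault((iv.ref_id, iv.strand), []).append((iv, rid))
    contigs: list[Contig] = []
    for (ref_id, strand), items in sorted(by_group.items()):
        items.sort(key=lambda t: (t[0].start, t[0].end, t[1]))
        cur_start = cur_end = None
        cur_reads: list[str] = []
        for iv, rid in items:
            if cur_end is not None and min(iv.end, cur_end) - iv.start >= cfg.contig_overlap:
                cur_end = max(cur_end, iv.end)
                cur_reads.append(rid)
            else:
                if cur_end is not None and len(cur_reads) >= cfg.min_contig_reads:
                    contigs.append(
                        Contig(GenomicInterval(ref_id, cur_start, cur_end, strand),
                               cur_reads, sample_id)
                    )
                cur_start, cur_end, cur_reads = iv.start, iv.end, [rid]
        if cur_end is not None and len(cur_reads) >= cfg.min_contig_reads:
            contigs.append(
                Contig(GenomicInterval(ref_id, cur_start, cur_end, strand),
                       cur_reads, sample_id)
            )
    return contigs


def _union_runs(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Point-set union of half-open intervals as maximal disjoint runs."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(run) for run in out]


def _intersect_runs(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def condition_consensus(
    per_sample_contigs: dict[str, list[Contig]],
    condition: str,
    per_sample_intervals: dict[str, list[tuple[GenomicInterval, str]]] | None = None,
) -> list[ConsensusContig]:
    """Longest contig intervals present in *all* samples of a condition.

    Per reference and strand, the contig-covered positions of each sample are
    intersected; every maximal run of jointly covered positions becomes one
    consensus contig.  Per-sample supporting counts are recomputed as the
    number of that sample's alignments overlapping the consensus interval by
    at least one base (falling back to member-contig read tallies when the raw
    intervals are not supplied).
    """
    if not per_sample_contigs:
        raise ValueError(f"condition {condition!r} has no samples")
    samples = sorted(per_sample_contigs)
    groups: set[tuple[str, str]] = set()
    for contigs in per_sample_contigs.values():
        groups.update((c.interval.ref_id, c.interval.strand) for c in contigs)
    out: list[ConsensusContig] = []
    for ref_id, strand in sorted(groups):
        runs: list[tuple[int, int]] | None = None
        for sample in samples:
            covered = _union_runs(
                [
                    (c.interval.start, c.interval.end)
                    for c in per_sample_contigs[sample]
                    if c.interval.ref_id == ref_id and c.interval.strand == strand
                ]
            )
            runs = covered if runs is None else _intersect_runs(runs, covered)
            if not runs:
                break
        if not runs:
            continue
        for start, end in runs:
            iv = GenomicInterval(ref_id, start, end, strand)
            counts: dict[str, int] = {}
            for sample in samples:
                if per_sample_intervals is not None:
                    counts[sample] = sum(
                        1
                        for siv, _rid in per_sample_intervals[sample]
                        if siv.overlap(iv) >= 1
                    )
                else:
                    counts[sample] = sum(
                        c.read_count
                        for c in per_sample_contigs[sample]
                        if c.interval.overlap(iv) >= 1
                    )
            out.append(ConsensusContig(iv, condition, counts))
    return out


def unify_consensus(consensus_sets: list[list[ConsensusContig]]) -> list[ConsensusContig]:
    """Union of the conditions' consensus sets, deduplicating identical intervals.

    When the same interval is a consensus contig in several conditions, one
    entry is kept with the per-sample counts merged (sample ids are disjoint
    across conditions) and the condition labels joined with '+'.
    """
    merged: dict[tuple, ConsensusContig] = {}
    for contigs in consensus_sets:
        for c in contigs:
            key = c.key()
            if key in merged:
                prev = merged[key]
                prev.per_sample_read_counts.update(c.per_sample_read_counts)
                if c.condition not in prev.condition.split("+"):
                    prev.condition = f"{prev.condition}+{c.condition}"
            else:
                merged[key] = ConsensusContig(
                    c.interval, c.condition, dict(c.per_sample_read_counts)
                )
    return [merged[key] for key in sorted(merged)]


def write_contigs_bed(contigs: list[Contig], path: str | Path) -> None:
    """BED6: name = contig id, score = read count."""
    with open(path, "w") as handle:
        for i, c in enumerate(contigs):
            iv = c.interval
            handle.write(
                f"{iv.ref_id}\t{iv.start}\t{iv.end}\t"
                f"{c.sample_id}.contig{i}\t{c.read_count}\t{iv.strand}\n"
            )


def write_bedgraph(
    intervals: list[tuple[GenomicInterval, str]], strand: str, path: str | Path
) -> None:
    """Per-base coverage of one strand's intervals as bedGraph."""
    events: dict[str, list[tuple[int, int]]] = {}
    for iv, _rid in intervals:
        if iv.strand != strand:
            continue
        events.setdefault(iv.ref_id, []).append((iv.start, iv.end))
    with open(path, "w") as handle:
        for ref_id in sorted(events):
            points = sorted({p for s, e in events[ref_id] for p in (s, e)})
            for lo, hi in zip(points, points[1:]):
                depth = sum(1 for s, e in events[ref_id] if s <= lo and e >= hi)
                if depth > 0:
                    handle.write(f"{ref_id}\t{lo}\t{hi}\t{depth}\n")


def write_consensus_tsv(contigs: list[ConsensusContig], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["ref_id", "start", "end", "strand", "condition", "per_sample_counts"])
        for c in contigs:
            iv = c.interval
            counts = ",".join(f"{s}:{n}" for s, n in sorted(c.per_sample_read_counts.items()))
            writer.writerow([iv.ref_id, iv.start, iv.end, iv.strand, c.condition, counts])
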