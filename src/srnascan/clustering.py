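"""Greedy representative-contig clustering and final feature-set assembly.

Multimapped reads make the same transcript appear as several contigs at
duplicated loci.  The clustering repeatedly selects, among the unclustered
contigs, the one with the highest read count (ties: longest, then a seeded
random choice) as the representative contig (RC), absorbs every other
unclustered contig whose supporting reads are shared with the RC at a
fraction of at least ``share_frac``, and emits the cluster; this continues
until no contig is left.  The sharing fraction is directional by default,
measured over the candidate member's reads (|c ∩ RC| / |c|), so low-count
shadows of a dominant locus are absorbed; a Jaccard variant is available via
``config.jaccard_sharing``.

A read contributes *identity* (its id) to sharing fractions but
*multiplicity* (one per placement) to read counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .contigs import ConsensusContig, GenomicInterval

__all__ = ["Cluster", "KnownFeature", "Feature", "cluster_contigs", "assemble_feature_set",
           "write_clusters_tsv"]


@dataclass
class Cluster:
    representative: ConsensusContig
    members: list[ConsensusContig] = field(default_factory=list)

    @property
    def total_read_count(self) -> int:
        return self.representative.read_count + sum(m.read_count for m in self.members)


def _read_set(read_map, contig: ConsensusContig) -> frozenset:
    for key in (contig.key(), id(contig)):
        if key in read_map:
            return frozenset(read_map[key])
    try:
        return frozenset(read_map[contig])  # type: ignore[index]
    except (KeyError, TypeError):
        iv = contig.interval
        raise KeyError(
            f"contig {iv.ref_id}:{iv.start}-{iv.end}({iv.strand}) missing from read_map"
        ) from None


def cluster_contigs(
    contigs: list[ConsensusContig],
    read_map: dict,
    config: PipelineConfig | None = None,
    rng_seed: int | None = None,
) -> list[Cluster]:
    """Greedy RC clustering; deterministic given ``rng_seed``.

    ``read_map`` maps each contig (keyed by its ``key()`` tuple) to the set of
    read ids supporting it; multimapped reads appear in several contigs' sets.
    """
    cfg = config or PipelineConfig()
    seed = cfg.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    items = [(c, _read_set(read_map, c)) for c in contigs]
    clusters: list[Cluster] = []
    while items:
        counts = [c.read_count for c, _ in items]
        best_count = max(counts)
        tied = [i for i, n in enumerate(counts) if n == best_count]
        if len(tied) > 1:
            best_len = max(len(items[i][0].interval) for i in tied)
            tied = [i for i in tied if len(items[i][0].interval) == best_len]
        if len(tied) > 1:
            rc_idx = tied[int(rng.integers(len(tied)))]
        else:
            rc_idx = tied[0]
        rc, rc_reads = items[rc_idx]
        members: list[ConsensusContig] = []
        remaining: list[tuple[ConsensusContig, frozenset]] = []
        for i, (c, c_reads) in enumerate(items):
            if i == rc_idx:
                continue
            shared = c_reads & rc_reads
            if shared:
                if cfg.jaccard_sharing:
                    frac = len(shared) / len(c_reads | rc_reads)
                else:
                    frac = len(shared) / len(c_reads) if c_reads else 0.0
                if frac >= cfg.share_frac:
                    members.append(c)
                    continue
            remaining.append((c, c_reads))
        clusters.append(Cluster(rc, members))
        items = remaining
    return clusters


@dataclass(frozen=True)
class KnownFeature:
    """A round-1 feature: one reference sequence with its annotation identity."""

    ref_id: str
    name: str  # annotation name used for duplicate removal
    biotype: str = ""


@dataclass
class Feature:
    """An entry of the final quantified feature set (known or novel)."""

    feature_id: str
    kind: str  # 'known' or 'novel'
    name: str | None = None
    ref_ids: tuple[str, ...] = ()
    interval: GenomicInterval | None = None
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("known", "novel"):
            raise ValueError(f"feature kind must be known/novel, got {self.kind!r}")


def assemble_feature_set(
    known_round1_features: list[KnownFeature],
    novel_clusters: list[Cluster],
) -> list[Feature]:
    """Deduplicate known features by annotation name and append novel loci.

    Known reference entries sharing an annotation name (the same gene drawn
    from two source sets, or duplicated copies) collapse to one feature whose
    ``ref_ids`` carries every member id, so downstream counting sums over the
    duplicates.  Novel clusters contribute their representative locus.  Order
    is deterministic: known sorted by name, then novel by coordinate.
    """
    by_name: dict[str, list[KnownFeature]] = {}
    for kf in known_round1_features:
        by_name.setdefault(kf.name, []).append(kf)
    features = [
        Feature(
            feature_id=name,
            kind="known",
            name=name,
            ref_ids=tuple(sorted({kf.ref_id for kf in group})),
            biotype=group[0].biotype,
        )
        for name, group in sorted(by_name.items())
    ]
    novel = sorted(novel_clusters, key=lambda cl: cl.representative.key())
    for cl in novel:
        iv = cl.representative.interval
        features.append(
            Feature(
                feature_id=f"novel:{iv.ref_id}:{iv.start}-{iv.end}({iv.strand})",
                kind="novel",
                interval=iv,
            )
        )
    return features


def write_clusters_tsv(clusters: list[Cluster], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["ref_id", "start", "end", "strand", "n_members", "total_reads", "member_ids"]
        )
        for cl in clusters:
            iv = cl.representative.interval
            member_ids = ";".join(
                f"{m.interval.ref_id}:{m.interval.start}-{m.interval.end}({m.interval.strand})"
                for m in cl.members
            )
            writer.writerow(
                [iv.ref_id, iv.start, iv.end, iv.strand, len(cl.members),
                 cl.total_read_count, member_ids]
            )
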