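"""Feature annotation: assign ncRNA identity and class.

Known round-1 features inherit the identity of the reference sequence they
aligned to.  Novel genomic loci are intersected with annotation tracks
(GTF/GFF or BED with biotype) in priority order: within the highest-priority
source that overlaps a feature on the same strand, the annotation with the
largest reciprocal overlap wins.  A feature overlapped only on the opposite
strand is classed ``antisense``; a feature overlapping nothing is ``novel``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path

from intervaltree import IntervalTree

from .clustering import Feature
from .contigs import GenomicInterval
from .reference import ReferenceSequence, annotation_name

__all__ = [
    "AnnotationRecord",
    "AnnotatedFeature",
    "CLASSES",
    "annotate_features",
    "classify_round1_feature",
    "normalize_biotype",
    "read_annotation_bed",
    "read_annotation_gtf",
    "write_annotated_tsv",
]

CLASSES = (
    "miRNA", "tRNA", "mt_tRNA", "snoRNA", "snRNA", "lincRNA", "antisense", "repeat", "novel",
)

_BIOTYPE_MAP = {
    "mirna": "miRNA",
    "mirna_mature": "miRNA",
    "trna": "tRNA",
    "mt_trna": "mt_tRNA",
    "mt-trna": "mt_tRNA",
    "snorna": "snoRNA",
    "snrna": "snRNA",
    "lincrna": "lincRNA",
    "lncrna": "lincRNA",
    "antisense": "antisense",
    "repeat": "repeat",
}


def normalize_biotype(biotype: str) -> str:
    """Map an annotation biotype onto the closed class vocabulary.

    Mitochondrial tRNA spellings and common lncRNA synonyms are recognised;
    anything unrecognised falls into the generic lincRNA bucket so the class
    set stays closed.
    """
    return _BIOTYPE_MAP.get(biotype.strip().lower(), "lincRNA")


@dataclass(frozen=True)
class AnnotationRecord:
    interval: GenomicInterval
    name: str
    biotype: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("annotation name must be non-empty")


@dataclass
class AnnotatedFeature:
    feature_id: str
    location: GenomicInterval | str  # genomic interval or reference-sequence id
    assigned_name: str | None
    assigned_class: str
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.assigned_class not in CLASSES:
            raise ValueError(f"unknown class {self.assigned_class!r}")
        if (self.assigned_class == "novel") != (self.assigned_name is None):
            raise ValueError("class is 'novel' exactly when no name is assigned")


def _build_trees(records: list[AnnotationRecord]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for rec in records:
        iv = rec.interval
        trees.setdefault((iv.ref_id, iv.strand), IntervalTree()).addi(iv.start, iv.end, rec)
    return trees


def _best_hit(
    feature_iv: GenomicInterval,
    trees: dict[tuple[str, str], IntervalTree],
    strand: str,
) -> tuple[AnnotationRecord, float] | None:
    tree = trees.get((feature_iv.ref_id, strand))
    if tree is None:
        return None
    hits = tree.overlap(feature_iv.start, feature_iv.end)
    best: tuple[float, str, AnnotationRecord] | None = None
    for hit in hits:
        rec: AnnotationRecord = hit.data
        ov = min(feature_iv.end, rec.interval.end) - max(feature_iv.start, rec.interval.start)
        if ov < 1:
            continue
        recip = min(ov / len(feature_iv), ov / len(rec.interval))
        # largest reciprocal overlap wins; ties broken by name for determinism
        if best is None or (recip, ) > (best[0], ) or (recip == best[0] and rec.name < best[1]):
            best = (recip, rec.name, rec)
    if best is None:
        return None
    return best[2], best[0]


def annotate_features(
    features: list[Feature],
    tracks: dict[str, list[AnnotationRecord]],
    priority: list[str] | None = None,
) -> list[AnnotatedFeature]:
    """Assign each novel feature a name and class from annotation tracks.

    ``tracks`` maps a source name to its records; ``priority`` orders the
    sources (first = highest).  Same-strand overlap is tried source by source;
    only when no same-strand annotation overlaps anywhere is an
    opposite-strand overlap reported as class ``antisense``.  Features of kind
    'known' must be classified via :func:`classify_round1_feature` instead and
    are rejected here.
    """
    order = priority if priority is not None else sorted(tracks)
    trees = {src: _build_trees(tracks[src]) for src in order}
    out: list[AnnotatedFeature] = []
    for feature in features:
        if feature.kind != "novel" or feature.interval is None:
            raise ValueError(
                f"annotate_features expects novel features with intervals, got {feature.feature_id}"
            )
        iv = feature.interval
        assigned: AnnotatedFeature | None = None
        for src in order:
            hit = _best_hit(iv, trees[src], iv.strand)
            if hit is not None:
                rec, frac = hit
                assigned = AnnotatedFeature(
                    feature.feature_id, iv, rec.name, normalize_biotype(rec.biotype), frac
                )
                break
        if assigned is None:
            other = "-" if iv.strand == "+" else "+"
            for src in order:
                hit = _best_hit(iv, trees[src], other)
                if hit is not None:
                    rec, frac = hit
                    assigned = AnnotatedFeature(
                        feature.feature_id, iv, rec.name, "antisense", frac
                    )
                    break
        if assigned is None:
            assigned = AnnotatedFeature(feature.feature_id, iv, None, "novel", 0.0)
        out.append(assigned)
    return out


_SOURCE_CLASS = {
    "mirna_mature": "miRNA",
    "trna": "tRNA",
    "mt_trna": "mt_tRNA",
    "snorna": "snoRNA",
}


def classify_round1_feature(
    ref_id: str, reference: dict[str, ReferenceSequence]
) -> AnnotatedFeature:
    """Class of a feature aligned to the custom reference, from its metadata.

    The dedicated source sets determine the class directly; Ensembl entries
    fall back to their biotype; mitochondrial tRNAs are also recognised by the
    conventional ``MT-T`` name prefix.
    """
    try:
        rec = reference[ref_id]
    except KeyError:
        raise KeyError(f"unknown reference sequence id {ref_id!r}") from None
    name = annotation_name(ref_id)
    if rec.source_set in _SOURCE_CLASS:
        cls = _SOURCE_CLASS[rec.source_set]
    elif name.upper().startswith("MT-T") or rec.biotype.lower() in ("mt_trna", "mt-trna"):
        cls = "mt_tRNA"
    elif rec.biotype:
        cls = normalize_biotype(rec.biotype)
    else:
        cls = "lincRNA"
    return AnnotatedFeature(name, ref_id, name, cls, 1.0)


def read_annotation_bed(path: str | Path) -> list[AnnotationRecord]:
    """Read BED6 annotations; an optional 7th column carries the biotype."""
    out = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{line_no}: BED6 requires 6 columns")
            ref_id, start, end, name, _score, strand = parts[:6]
            biotype = parts[6] if len(parts) > 6 else ""
            out.append(
                AnnotationRecord(
                    GenomicInterval(ref_id, int(start), int(end), strand), name, biotype
                )
            )
    return out


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation_gtf(
    path: str | Path,
    feature_types: tuple[str, ...] = ("gene", "transcript", "exon"),
    name_key: str = "gene_name",
    biotype_key: str = "gene_biotype",
) -> list[AnnotationRecord]:
    """Read GTF/GFF annotations, keeping one record per named feature line."""
    out = []
    seen: set[tuple] = set()
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{line_no}: GTF requires 9 columns")
            ref_id, _src, ftype, start, end, _score, strand, _frame, attrs = parts[:9]
            if ftype not in feature_types or strand not in "+-":
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            name = attr.get(name_key) or attr.get("gene_id") or ""
            if not name:
                continue
            iv = GenomicInterval(ref_id, int(start) - 1, int(end), strand)
            key = (iv.ref_id, iv.start, iv.end, iv.strand, name)
            if key in seen:
                continue
            seen.add(key)
            out.append(AnnotationRecord(iv, name, attr.get(biotype_key, "")))
    return out


def write_annotated_tsv(annotated: list[AnnotatedFeature], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["feature_id", "location", "assigned_name", "assigned_class",
                         "overlap_fraction"])
        for af in annotated:
            if isinstance(af.location, GenomicInterval):
                loc = (f"{af.location.ref_id}:{af.location.start}-"
                       f"{af.location.end}({af.location.strand})")
            else:
                loc = af.location
            writer.writerow(
                [af.feature_id, loc, af.assigned_name or "", af.assigned_class,
                 f"{af.overlap_fraction:.4f}"]
            )
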