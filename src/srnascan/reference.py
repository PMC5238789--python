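"""Custom small-ncRNA reference construction.

Round 1 of the mapping strategy aligns reads against a dedicated reference of
known small ncRNA sequences (Ensembl ncRNA entries capped at 400 nt, mature
miRNAs, snoRNAs, nuclear and mitochondrial tRNAs).  This module validates,
length-filters and deduplicates whatever FASTA the user supplies; it never
downloads anything.

Reference ids may carry a ``|source`` suffix (e.g. ``hsa-miR-21-5p|mirbase``)
so that the same annotated gene contributed by two source sets remains
distinguishable; the part before ``|`` is the *annotation name* used when
known features are deduplicated downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import PipelineConfig

__all__ = [
    "ReferenceSequence",
    "SOURCE_SETS",
    "build_ncrna_reference",
    "annotation_name",
    "read_reference_fasta",
    "write_reference_fasta",
    "ReferenceError",
]

SOURCE_SETS = ("ensembl_ncrna", "mirna_mature", "snorna", "trna", "mt_trna", "other")
_ALPHABET = set("ACGTN")


class ReferenceError(ValueError):
    """Raised for invalid reference sequences or ambiguous duplicate ids."""


@dataclass(frozen=True)
class ReferenceSequence:
    """One entry of the custom ncRNA reference (DNA alphabet)."""

    id: str
    sequence: str
    source_set: str = "other"
    biotype: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ReferenceError("reference sequence id must be non-empty")
        if not self.sequence:
            raise ReferenceError(f"reference sequence {self.id!r} is empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ReferenceError(
                f"reference sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )
        if self.source_set not in SOURCE_SETS:
            raise ReferenceError(
                f"reference sequence {self.id!r}: unknown source_set {self.source_set!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def annotation_name(ref_id: str) -> str:
    """Annotation name of a reference id: the part before any ``|source`` tag."""
    return ref_id.split("|", 1)[0]


def build_ncrna_reference(
    sequences: list[ReferenceSequence], config: PipelineConfig | None = None
) -> list[ReferenceSequence]:
    """Build the round-1 reference: length-cap, deduplicate, sort.

    Keeps every input sequence of length <= ``config.max_ncrna_len`` (the
    focus is small ncRNAs, so the reference is capped rather than exact-length
    restricted).  Exact duplicates (same id, same sequence) collapse to one
    entry; the same id with two different sequences is an ambiguous reference
    and raises.  Output order is deterministic (sorted by id), which makes the
    operation idempotent.
    """
    max_len = (config or PipelineConfig()).max_ncrna_len
    seen: dict[str, ReferenceSequence] = {}
    for rec in sequences:
        if len(rec) > max_len:
            continue
        prev = seen.get(rec.id)
        if prev is None:
            seen[rec.id] = rec
        elif prev.sequence != rec.sequence:
            raise ReferenceError(
                f"duplicate reference id {rec.id!r} with conflicting sequences"
            )
    return [seen[key] for key in sorted(seen)]


def read_reference_fasta(
    fasta_path: str | Path, metadata_path: str | Path | None = None
) -> list[ReferenceSequence]:
    """Read reference sequences from FASTA plus an optional metadata sidecar.

    The sidecar is a TSV with columns ``id``, ``biotype``, ``source_set``.
    Sequences are uppercased and U is converted to T (references are stored in
    the DNA alphabet regardless of how the source FASTA writes RNA).
    """
    meta: dict[str, tuple[str, str]] = {}
    if metadata_path is not None:
        with open(metadata_path, newline="") as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                meta[row["id"]] = (row.get("biotype", ""), row.get("source_set", "other"))
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        biotype, source_set = meta.get(rec.id, ("", "other"))
        seq = str(rec.seq).upper().replace("U", "T")
        out.append(ReferenceSequence(rec.id, seq, source_set, biotype))
    return out


def write_reference_fasta(
    sequences: list[ReferenceSequence],
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in sequences]
    SeqIO.write(records, str(fasta_path), "fasta")
    if metadata_path is not None:
        with open(metadata_path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "biotype", "source_set"])
            for r in sequences:
                writer.writerow([r.id, r.biotype, r.source_set])
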