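"""Read preprocessing: 3' adapter trimming and length/quality filtering.

Small-RNA inserts are shorter than the sequencing read, so the 3' end of a
read frequently runs into the library adapter.  Trimming removes the longest
read suffix that matches a prefix of the adapter within an error budget; a
subsequent filter drops reads shorter than 16 nt (sub-miRNA fragments that
cannot be placed reliably) and, when base qualities are present, reads whose
mean quality falls below a floor.  5' adapters are not handled: the library
chemistry this models leaves adapter sequence only at the 3' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "TrimReport",
    "trim_adapter",
    "filter_reads",
    "preprocess_reads",
    "read_fastq",
    "write_fastq",
]

_PHRED_OFFSET = 33


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; quality is a tuple of Phred scores or ``None``."""

    read_id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TrimReport:
    """Per-sample preprocessing tallies, written to the trimming report TSV."""

    sample_id: str = ""
    reads_in: int = 0
    reads_trimmed: int = 0
    reads_dropped_short: int = 0
    reads_dropped_quality: int = 0

    @property
    def reads_out(self) -> int:
        return self.reads_in - self.reads_dropped_short - self.reads_dropped_quality


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    min_overlap: int = 3,
    max_err_rate: float = 0.1,
) -> ReadRecord:
    """Remove the longest read suffix matching a prefix of ``adapter``.

    A suffix of length ``ov`` qualifies when ``ov >= min_overlap`` and the
    number of mismatches against ``adapter[:ov]`` is at most
    ``max_err_rate * ov``.  The longest qualifying overlap wins; with no
    qualifying overlap the read is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    best = 0
    max_ov = min(len(seq), len(adapter))
    for ov in range(min_overlap, max_ov + 1):
        suffix = seq[len(seq) - ov :]
        mism = sum(a != b for a, b in zip(suffix, adapter))
        if mism <= max_err_rate * ov:
            best = ov
    if best == 0:
        return read
    keep = len(seq) - best
    quality = read.quality[:keep] if read.quality is not None else None
    return ReadRecord(read.read_id, seq[:keep], quality)


def filter_reads(
    reads: list[ReadRecord],
    config: PipelineConfig | None = None,
    report: TrimReport | None = None,
) -> list[ReadRecord]:
    """Drop reads shorter than ``min_read_len`` or below the mean-quality floor.

    Relative order of surviving reads is preserved.  Drop counts are logged
    and, when a :class:`TrimReport` is supplied, accumulated into it.
    """
    cfg = config or PipelineConfig()
    kept: list[ReadRecord] = []
    n_short = n_qual = 0
    for read in reads:
        if len(read) < cfg.min_read_len:
            n_short += 1
            continue
        if read.quality is not None and len(read.quality) > 0:
            if sum(read.quality) / len(read.quality) < cfg.min_mean_quality:
                n_qual += 1
                continue
        kept.append(read)
    logger.info(
        "filter_reads: %d in, %d dropped short (<%d nt), %d dropped low quality",
        len(reads), n_short, cfg.min_read_len, n_qual,
    )
    if report is not None:
        report.reads_dropped_short += n_short
        report.reads_dropped_quality += n_qual
    return kept


def preprocess_reads(
    reads: list[ReadRecord],
    config: PipelineConfig | None = None,
    sample_id: str = "",
) -> tuple[list[ReadRecord], TrimReport]:
    """Trim (when an adapter is configured) then length/quality filter."""
    cfg = config or PipelineConfig()
    report = TrimReport(sample_id=sample_id, reads_in=len(reads))
    if cfg.adapter:
        trimmed = []
        for read in reads:
            out = trim_adapter(read, cfg.adapter, cfg.adapter_min_overlap, cfg.adapter_max_err_rate)
            if len(out) < len(read):
                report.reads_trimmed += 1
            trimmed.append(out)
        reads = trimmed
    kept = filter_reads(reads, cfg, report)
    return kept, report


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a 4-line-record FASTQ (Phred+33)."""
    out = []
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            read_id = title.split()[0]
            quality = tuple(ord(c) - _PHRED_OFFSET for c in qual)
            out.append(ReadRecord(read_id, seq.upper(), quality))
    return out


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            if read.quality is None:
                qual = "I" * len(read)  # Q40 placeholder
            else:
                qual = "".join(chr(q + _PHRED_OFFSET) for q in read.quality)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
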