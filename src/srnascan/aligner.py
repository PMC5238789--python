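"""Two-round multimap-aware short-read alignment.

Round 1 places reads on a dedicated small-ncRNA reference: 3' soft-clipping is
permitted as long as at least ``round1_min_match`` bases align, and the
mismatch fraction over the *matched* length must stay below
``round1_mismatch_ratio``.  Round 2 takes round 1's unmapped reads to the
genome end-to-end (no clipping), with the mismatch fraction over the *read*
length below ``round2_mismatch_ratio`` and a minimum read length of
``round2_min_match``.  In both rounds only placements tying the best score
(fewest mismatches, then longest matched length) are reported, each tagged
with the total number of co-optimal placements (``n_hits``); reads exceeding
``max_hits`` placements are routed to the unmapped set.

The built-in engine is k-mer seeded (every read position, default seed length
10, which by a pigeonhole argument over the permitted mismatch budgets cannot
miss a qualifying placement) with full ungapped verification at each candidate
diagonal.  It is intended for references up to the tens of megabases; larger
genomes should go through an external aligner and :func:`import_alignments`.
Indels and spliced alignment are deliberately not modelled: the targets are
16-200 nt ncRNAs and the mapping strategy disables splicing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import PipelineConfig
from .preprocess import ReadRecord
from .reference import ReferenceSequence

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "MappingResult",
    "map_round1",
    "map_round2",
    "import_alignments",
    "write_sam",
    "reverse_complement",
]

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3; anything else (N) -> 4, which never matches."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentRecord:
    """One placement of one read; a k-fold multimapper yields k records."""

    read_id: str
    ref_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'
    mismatches: int
    matched_len: int
    n_hits: int
    round: int  # 1 or 2

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"alignment {self.read_id}: start >= end")
        if self.strand not in "+-":
            raise ValueError(f"alignment {self.read_id}: bad strand {self.strand!r}")
        if self.n_hits < 1:
            raise ValueError(f"alignment {self.read_id}: n_hits < 1")


@dataclass
class MappingResult:
    alignments: list[AlignmentRecord] = field(default_factory=list)
    unmapped_read_ids: set[str] = field(default_factory=set)

    @property
    def mapped_read_ids(self) -> set[str]:
        return {a.read_id for a in self.alignments}


class _RefSet:
    """All reference sequences concatenated behind one exact k-mer index.

    Segments are separated by runs of the invalid code so no k-mer window and
    no verified placement can span a sequence boundary.
    """

    def __init__(self, references: dict[str, str], k: int):
        self.k = k
        self.ids = list(references)
        starts, parts = [], []
        cursor = 0
        sep = np.full(k, 4, dtype=np.uint8)
        for ref_id in self.ids:
            codes = _encode(references[ref_id])
            starts.append(cursor)
            parts.append(codes)
            cursor += codes.size
            parts.append(sep)
            cursor += k
        self.codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        self.seg_starts = np.asarray(starts, dtype=np.int64)
        self.seg_ends = self.seg_starts + np.asarray(
            [len(references[r]) for r in self.ids], dtype=np.int64
        )
        n = self.codes.size
        if n < k:
            self._hashes = np.empty(0, dtype=np.int64)
            self._positions = np.empty(0, dtype=np.int64)
            return
        win = sliding_window_view(self.codes, k)
        valid = (win < 4).all(axis=1)
        powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
        hashes = win.astype(np.int64) @ powers
        pos = np.nonzero(valid)[0]
        hashes = hashes[valid]
        order = np.argsort(hashes, kind="stable")
        self._hashes = hashes[order]
        self._positions = pos[order]

    def segment_of(self, pos: int) -> int:
        """Index of the segment containing global position ``pos`` (or -1)."""
        i = int(np.searchsorted(self.seg_starts, pos, side="right")) - 1
        if i < 0 or pos >= self.seg_ends[i]:
            return -1
        return i

    def hit_pairs(self, qpos: np.ndarray, qhashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(reference positions, matching query seed positions) of all seed hits."""
        if qhashes.size == 0 or self._hashes.size == 0:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        lo = np.searchsorted(self._hashes, qhashes, side="left")
        hi = np.searchsorted(self._hashes, qhashes, side="right")
        counts = hi - lo
        nz = np.nonzero(counts)[0]
        if nz.size == 0:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        hits = np.concatenate([self._positions[lo[i] : hi[i]] for i in nz])
        qp = np.repeat(qpos[nz], counts[nz])
        return hits, qp


def _query_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, hashes) of all valid k-mers of the query."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    hashes = win.astype(np.int64) @ powers
    pos = np.nonzero(valid)[0]
    return pos, hashes[valid]


def _best_clipped(
    q: np.ndarray, ref: np.ndarray, start: int, min_match: int, ratio: float
) -> tuple[int, int] | None:
    """Best (mismatches, L) for a prefix of ``q`` anchored at ``ref[start:]``.

    A length L qualifies when L >= min_match and mismatches/L < ratio.  Best is
    fewest mismatches, then longest L.  Returns None when nothing qualifies.
    """
    lmax = min(q.size, ref.size - start)
    if lmax < min_match:
        return None
    window = ref[start : start + lmax]
    diff = (q[:lmax] != window) | (q[:lmax] > 3) | (window > 3)
    cum = np.cumsum(diff)
    lengths = np.arange(min_match, lmax + 1)
    mism = cum[lengths - 1]
    ok = mism < ratio * lengths
    if not ok.any():
        return None
    best_m = int(mism[ok].min())
    best_l = int(lengths[ok & (mism == best_m)].max())
    return best_m, best_l


def _map_unique_seq(
    seq: str,
    refset: _RefSet,
    *,
    min_match: int,
    ratio: float,
    end_to_end: bool,
    k: int,
) -> list[tuple[str, int, int, str, int, int]]:
    """All best-score placements of one read sequence.

    Returns tuples (ref_id, start, end, strand, mismatches, matched_len).
    """
    n = len(seq)
    if n < min_match:
        return []
    placements: list[tuple[int, int, str, int, int, int]] = []
    # (mismatches, -L) is the score; collect every qualifying candidate first
    queries = {"+": _encode(seq), "-": _encode(reverse_complement(seq))}
    for strand, q in queries.items():
        qpos, qhash = _query_hashes(q, k)
        hits, qp = refset.hit_pairs(qpos, qhash)
        if hits.size == 0:
            continue
        if end_to_end or strand == "+":
            anchors = np.unique(hits - qp)  # placement (or matched-prefix) start
        else:
            anchors = np.unique(hits + (n - qp))  # end of the matched suffix
        for anchor_np in anchors:
            anchor = int(anchor_np)
            if end_to_end:
                seg = refset.segment_of(anchor)
                if seg < 0:
                    continue
                s0, s1 = int(refset.seg_starts[seg]), int(refset.seg_ends[seg])
                if anchor + n > s1:
                    continue
                window = refset.codes[anchor : anchor + n]
                m = int(((q != window) | (q > 3) | (window > 3)).sum())
                if m < ratio * n:
                    placements.append((m, n, strand, seg, anchor - s0, anchor - s0 + n))
            elif strand == "+":
                seg = refset.segment_of(anchor)
                if seg < 0:
                    continue
                s0, s1 = int(refset.seg_starts[seg]), int(refset.seg_ends[seg])
                best = _best_clipped(q, refset.codes[s0:s1], anchor - s0, min_match, ratio)
                if best is not None:
                    m, L = best
                    placements.append((m, L, strand, seg, anchor - s0, anchor - s0 + L))
            else:
                seg = refset.segment_of(anchor - 1)  # anchor is an exclusive end
                if seg < 0:
                    continue
                s0, s1 = int(refset.seg_starts[seg]), int(refset.seg_ends[seg])
                e_local = anchor - s0
                if e_local < min_match:
                    continue
                # match a suffix of q ending at local position e: reverse both
                best = _best_clipped(
                    q[::-1], refset.codes[s0 : s0 + e_local][::-1], 0, min_match, ratio
                )
                if best is not None:
                    m, L = best
                    placements.append((m, L, strand, seg, e_local - L, e_local))
    if not placements:
        return []
    best_m = min(p[0] for p in placements)
    best_l = max(p[1] for p in placements if p[0] == best_m)
    out = []
    for m, L, strand, seg, s, e in placements:
        if m == best_m and L == best_l:
            out.append((refset.ids[seg], s, e, strand, m, L))
    out.sort(key=lambda t: (t[0], t[1], t[3]))
    return out


def _run_round(
    reads: list[ReadRecord],
    references: dict[str, str],
    config: PipelineConfig,
    *,
    min_match: int,
    ratio: float,
    end_to_end: bool,
    round_no: int,
) -> MappingResult:
    if not references:
        raise ValueError("reference is empty")
    k = config.seed_length
    refset = _RefSet(references, k)
    result = MappingResult()
    # identical read sequences share one alignment computation
    by_seq: dict[str, list[str]] = {}
    for read in reads:
        by_seq.setdefault(read.sequence, []).append(read.read_id)
    discarded_multi = 0
    for seq, read_ids in by_seq.items():
        placements = _map_unique_seq(
            seq, refset, min_match=min_match, ratio=ratio, end_to_end=end_to_end, k=k
        )
        n_hits = len(placements)
        if n_hits == 0 or n_hits > config.max_hits:
            if n_hits > config.max_hits:
                discarded_multi += len(read_ids)
            result.unmapped_read_ids.update(read_ids)
            continue
        for read_id in read_ids:
            for ref_id, s, e, strand, m, L in placements:
                result.alignments.append(
                    AlignmentRecord(read_id, ref_id, s, e, strand, m, L, n_hits, round_no)
                )
    if discarded_multi:
        logger.info(
            "round %d: %d reads exceeded the %d-placement multimap cap",
            round_no, discarded_multi, config.max_hits,
        )
    return result


def _as_ref_dict(reference) -> dict[str, str]:
    if isinstance(reference, dict):
        return reference
    return {r.id: r.sequence for r in reference}


def map_round1(
    reads: list[ReadRecord],
    ncrna_ref: list[ReferenceSequence] | dict[str, str],
    config: PipelineConfig | None = None,
) -> MappingResult:
    """Round 1: clipped alignment against the custom small-ncRNA reference."""
    cfg = config or PipelineConfig()
    return _run_round(
        reads,
        _as_ref_dict(ncrna_ref),
        cfg,
        min_match=cfg.round1_min_match,
        ratio=cfg.round1_mismatch_ratio,
        end_to_end=False,
        round_no=1,
    )


def map_round2(
    unmapped_reads: list[ReadRecord],
    genome_ref: dict[str, str],
    config: PipelineConfig | None = None,
) -> MappingResult:
    """Round 2: end-to-end alignment of round-1 leftovers against the genome."""
    cfg = config or PipelineConfig()
    return _run_round(
        unmapped_reads,
        _as_ref_dict(genome_ref),
        cfg,
        min_match=cfg.round2_min_match,
        ratio=cfg.round2_mismatch_ratio,
        end_to_end=True,
        round_no=2,
    )


def import_alignments(path: str | Path, round_no: int = 2) -> MappingResult:
    """Convert an external SAM/BAM file into a :class:`MappingResult`.

    ``n_hits`` comes from the NH tag when present; otherwise it falls back to
    the per-read record tally.  A disagreement between the two is tolerated
    (the tag wins) but logged.
    """
    import pysam

    result = MappingResult()
    tallies: dict[str, int] = {}
    nh_tags: dict[str, int] = {}
    records: list[tuple] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    try:
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as handle:
            for i, rec in enumerate(handle):
                if rec.is_unmapped:
                    result.unmapped_read_ids.add(rec.query_name)
                    continue
                matched = sum(
                    length for op, length in (rec.cigartuples or []) if op in (0, 7, 8)
                )
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                records.append(
                    (
                        rec.query_name,
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        "-" if rec.is_reverse else "+",
                        int(nm),
                        matched,
                    )
                )
                tallies[rec.query_name] = tallies.get(rec.query_name, 0) + 1
                if rec.has_tag("NH"):
                    nh_tags[rec.query_name] = int(rec.get_tag("NH"))
    except (ValueError, OSError) as exc:
        raise ValueError(f"unparseable alignment file {path}: {exc}") from exc
    for qname, nh in nh_tags.items():
        if nh != tallies.get(qname, 0):
            logger.warning(
                "read %s: NH tag %d != %d records in file; keeping the tag",
                qname, nh, tallies[qname],
            )
    result.unmapped_read_ids -= set(tallies)
    for qname, ref_id, start, end, strand, nm, matched in records:
        n_hits = nh_tags.get(qname, tallies[qname])
        result.alignments.append(
            AlignmentRecord(qname, ref_id, start, end, strand, nm, matched, n_hits, round_no)
        )
    return result


def write_sam(
    result: MappingResult,
    references: dict[str, str] | list[ReferenceSequence],
    path: str | Path,
    read_sequences: dict[str, str] | None = None,
) -> None:
    """Write alignments as SAM with NH/NM tags (soft clips for round-1 records)."""
    import pysam

    refs = _as_ref_dict(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in refs.items()],
    }
    tid = {name: i for i, name in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in sorted(
            result.alignments, key=lambda a: (a.ref_id, a.start, a.read_id, a.strand)
        ):
            seg = pysam.AlignedSegment()
            seg.query_name = aln.read_id
            seg.reference_id = tid[aln.ref_id]
            seg.reference_start = aln.start
            seg.flag = 16 if aln.strand == "-" else 0
            seq = (read_sequences or {}).get(aln.read_id)
            clip = (len(seq) - aln.matched_len) if seq is not None else 0
            if clip > 0:
                # the clipped 3' tail sits rightmost on '+', leftmost on '-'
                if aln.strand == "+":
                    seg.cigarstring = f"{aln.matched_len}M{clip}S"
                else:
                    seg.cigarstring = f"{clip}S{aln.matched_len}M"
            else:
                seg.cigarstring = f"{aln.matched_len}M"
            if seq is not None:
                seg.query_sequence = seq if aln.strand == "+" else reverse_complement(seq)
            seg.mapping_quality = 255
            seg.set_tag("NH", aln.n_hits)
            seg.set_tag("NM", aln.mismatches)
            out.write(seg)
        for read_id in sorted(result.unmapped_read_ids):
            seg = pysam.AlignedSegment()
            seg.query_name = read_id
            seg.flag = 4
            seq = (read_sequences or {}).get(read_id)
            if seq is not None:
                seg.query_sequence = seq
            out.write(seg)
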