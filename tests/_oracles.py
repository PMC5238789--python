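"""Independent reference implementations used only for cross-checking.

Each oracle implements the same contract as the production code through a
structurally different algorithm: exhaustive all-offsets scanning instead of
seeded lookup, pairwise-overlap connected components instead of a sorted
sweep, and a literal transcription of the greedy clustering rules.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# --------------------------------------------------------------------------
# aligner oracle: naive all-offsets Hamming scan


def _scan_one(
    query: str, ref: str, min_match: int, ratio: float, end_to_end: bool
) -> list[tuple[int, int, int, int]]:
    """All qualifying (start, end, mismatches, L) of a query in one reference.

    The query is matched in the given orientation with its 5' end anchored at
    every offset (prefix-anchored with 3' clipping unless end_to_end).
    """
    n, m_ref = len(query), len(ref)
    if n < min_match or m_ref < min_match:
        return []
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer((ref + "\x00" * n).encode(), dtype=np.uint8)
    windows = sliding_window_view(r, n)[: m_ref]  # one window per offset
    mismatch = windows != q
    mismatch |= windows == 0  # padding beyond the reference never matches
    mismatch |= (q == ord(b"N")) | (windows == ord(b"N"))
    cum = np.cumsum(mismatch, axis=1).astype(np.int64)
    lmax = np.minimum(n, m_ref - np.arange(m_ref))
    if end_to_end:
        m_full = cum[:, n - 1]
        ok = (lmax >= n) & (m_full < ratio * n)
        return [(int(s), int(s) + n, int(m_full[s]), n) for s in np.nonzero(ok)[0]]
    lengths = np.arange(min_match, n + 1)
    msub = cum[:, lengths - 1]  # (offset, candidate length)
    valid = (msub < ratio * lengths) & (lengths[None, :] <= lmax[:, None])
    # per offset: fewest mismatches then longest length
    score = np.where(valid, msub * (2 * n + 2) - lengths, np.iinfo(np.int64).max)
    best_col = score.argmin(axis=1)
    has = valid.any(axis=1)
    out = []
    for s in np.nonzero(has)[0]:
        L = int(lengths[best_col[s]])
        out.append((int(s), int(s) + L, int(msub[s, best_col[s]]), L))
    return out


def naive_map(
    seq: str,
    references: dict[str, str],
    *,
    min_match: int,
    ratio: float,
    end_to_end: bool,
    suffix_anchored_minus: bool = True,
) -> list[tuple[str, int, int, str, int, int]]:
    """Best-score placements of one read by exhaustive scanning.

    Matches the production score rules: candidates per strand and offset, the
    plus strand prefix-anchored, the minus strand matching a suffix of the
    reverse complement (the read's 3' end clipped), then a global filter to
    the co-optimal (fewest mismatches, longest match) set.
    """
    candidates: list[tuple[int, int, str, str, int, int]] = []
    rc = revcomp(seq)
    for ref_id, ref in references.items():
        for s, e, m, L in _scan_one(seq, ref, min_match, ratio, end_to_end):
            candidates.append((m, L, ref_id, "+", s, e))
        if end_to_end or not suffix_anchored_minus:
            for s, e, m, L in _scan_one(rc, ref, min_match, ratio, end_to_end):
                candidates.append((m, L, ref_id, "-", s, e))
        else:
            # suffix-anchored: scan the reversed rc against the reversed ref
            ref_rev = ref[::-1]
            for s, e, m, L in _scan_one(rc[::-1], ref_rev, min_match, ratio, False):
                # positions map back as end = len(ref) - s
                end = len(ref) - s
                candidates.append((m, L, ref_id, "-", end - L, end))
    if not candidates:
        return []
    best_m = min(c[0] for c in candidates)
    best_l = max(c[1] for c in candidates if c[0] == best_m)
    out = [
        (ref_id, s, e, strand, m, L)
        for m, L, ref_id, strand, s, e in candidates
        if m == best_m and L == best_l
    ]
    out.sort(key=lambda t: (t[0], t[1], t[3]))
    return out


# --------------------------------------------------------------------------
# contig-merge oracle: pairwise linkage + connected components


def brute_merge(
    intervals_with_reads: list[tuple[tuple[str, int, int, str], str]],
    min_reads: int,
    min_overlap: int,
) -> list[tuple[str, int, int, str, int]]:
    """(ref, start, end, strand, read_count) per retained merged component."""
    out = []
    groups: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for (ref_id, start, end, strand), rid in intervals_with_reads:
        groups.setdefault((ref_id, strand), []).append((start, end, rid))
    for (ref_id, strand), items in groups.items():
        n = len(items)
        starts = np.array([s for s, _e, _r in items])
        ends = np.array([e for _s, e, _r in items])
        ov = np.minimum(ends[:, None], ends[None, :]) - np.maximum(
            starts[:, None], starts[None, :]
        )
        adj = ov >= min_overlap
        graph = coo_matrix(adj)
        n_comp, labels = connected_components(graph, directed=False)
        for comp in range(n_comp):
            members = np.nonzero(labels == comp)[0]
            count = len(members)
            if count >= min_reads:
                out.append(
                    (
                        ref_id,
                        int(starts[members].min()),
                        int(ends[members].max()),
                        strand,
                        count,
                    )
                )
    out.sort()
    return out


def brute_consensus(
    per_sample_intervals: dict[str, list[tuple[int, int]]], length: int
) -> list[tuple[int, int]]:
    """Maximal runs of positions covered in every sample (per-base marking)."""
    joint = np.ones(length, dtype=bool)
    for intervals in per_sample_intervals.values():
        covered = np.zeros(length, dtype=bool)
        for s, e in intervals:
            covered[s:e] = True
        joint &= covered
    runs = []
    start = None
    for i, flag in enumerate(joint):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, length))
    return runs


# --------------------------------------------------------------------------
# clustering oracle: literal greedy transcription


def naive_cluster(
    contigs: list[tuple[str, int, int]],
    read_sets: dict[str, frozenset],
    share_frac: float,
    seed: int,
) -> list[tuple[str, list[str]]]:
    """Greedy RC clustering over (name, read_count, length) tuples.

    Returns (representative, absorbed members) in emission order, making the
    same rng draws as the production code: one uniform integer draw exactly
    when the count-then-length tie leaves more than one candidate.
    """
    rng = np.random.default_rng(seed)
    pending = list(contigs)
    clusters = []
    while pending:
        max_count = max(c[1] for c in pending)
        tied = [c for c in pending if c[1] == max_count]
        if len(tied) > 1:
            max_len = max(c[2] for c in tied)
            tied = [c for c in tied if c[2] == max_len]
        rc = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
        rc_reads = read_sets[rc[0]]
        members = []
        survivors = []
        for c in pending:
            if c == rc:
                continue
            c_reads = read_sets[c[0]]
            if c_reads & rc_reads and c_reads and len(c_reads & rc_reads) / len(c_reads) >= share_frac:
                members.append(c[0])
            else:
                survivors.append(c)
        clusters.append((rc[0], members))
        pending = survivors
    return clusters


# --------------------------------------------------------------------------
# BH oracle: literal step-up formula


def bh_formula(pvalues) -> list[float]:
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = min(running_min, 1.0)
    return adjusted
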