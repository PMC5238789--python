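"""Contig assembly: interval conversion, merging, consensus."""

import numpy as np
import pytest

from _oracles import brute_consensus, brute_merge
from srnascan.aligner import AlignmentRecord
from srnascan.config import PipelineConfig
from srnascan.contigs import (
    Contig,
    GenomicInterval,
    alignments_to_intervals,
    condition_consensus,
    merge_contigs,
    unify_consensus,
)


def _iv(start, end, strand="+", ref="chr1"):
    return GenomicInterval(ref, start, end, strand)


def _pairs(spans, strand="+", prefix="r"):
    return [(_iv(s, e, strand), f"{prefix}{i}") for i, (s, e) in enumerate(spans)]


class TestAlignmentsToIntervals:
    def test_multimapper_contributes_one_interval_per_hit(self):
        alignments = [
            AlignmentRecord("r1", "chr1", s, s + 22, "+", 0, 22, 3, 2)
            for s in (10, 500, 900)
        ]
        out = alignments_to_intervals(alignments)
        assert len(out) == 3
        assert all(rid == "r1" for _iv_, rid in out)

    def test_empty_and_strand_preservation(self):
        assert alignments_to_intervals([]) == []
        alignments = [
            AlignmentRecord("a", "chr1", 0, 20, "+", 0, 20, 1, 2),
            AlignmentRecord("b", "chr1", 0, 20, "-", 0, 20, 1, 2),
        ]
        strands = {rid: iv.strand for iv, rid in alignments_to_intervals(alignments)}
        assert strands == {"a": "+", "b": "-"}


class TestMergeContigs:
    def test_five_identical_intervals_retained(self, config):
        contigs = merge_contigs(_pairs([(100, 122)] * 5), "s1", config)
        (contig,) = contigs
        assert contig.read_count == 5
        assert (contig.interval.start, contig.interval.end) == (100, 122)

    def test_four_reads_below_threshold(self, config):
        assert merge_contigs(_pairs([(100, 122)] * 4), "s1", config) == []

    def test_bookended_intervals_never_merge(self, config):
        pairs = _pairs([(0, 10)] * 5 + [(10, 20)] * 5)
        contigs = merge_contigs(pairs, "s1", config)
        assert [(c.interval.start, c.interval.end) for c in contigs] == [(0, 10), (10, 20)]

    def test_overlap_chain_merges_transitively(self, config):
        spans = [(0, 10)] * 3 + [(9, 20)] * 2 + [(19, 30)] * 2
        (contig,) = merge_contigs(_pairs(spans), "s1", config)
        assert (contig.interval.start, contig.interval.end) == (0, 30)
        assert contig.read_count == 7

    def test_strands_merged_separately(self, config):
        pairs = _pairs([(0, 30)] * 5, "+") + _pairs([(0, 30)] * 5, "-", prefix="m")
        contigs = merge_contigs(pairs, "s1", config)
        assert sorted(c.interval.strand for c in contigs) == ["+", "-"]

    @pytest.mark.parametrize("min_reads,overlap", [(5, 1), (6, 1), (2, 5)])
    def test_matches_bruteforce_on_random_sets(self, rng, min_reads, overlap):
        cfg = PipelineConfig(min_contig_reads=min_reads, contig_overlap=overlap)
        for _ in range(60):
            n = int(rng.integers(1, 120))
            starts = rng.integers(0, 400, size=n)
            lengths = rng.integers(16, 60, size=n)
            strands = rng.choice(["+", "-"], size=n)
            pairs = [
                (_iv(int(s), int(s + l), str(st)), f"r{i}")
                for i, (s, l, st) in enumerate(zip(starts, lengths, strands))
            ]
            got = sorted(
                (c.interval.ref_id, c.interval.start, c.interval.end,
                 c.interval.strand, c.read_count)
                for c in merge_contigs(pairs, "s", cfg)
            )
            expected = brute_merge(
                [((iv.ref_id, iv.start, iv.end, iv.strand), rid) for iv, rid in pairs],
                min_reads, overlap,
            )
            assert got == expected

    def test_read_conservation(self, rng, config):
        pairs = _pairs([(int(s), int(s) + 20) for s in rng.integers(0, 200, size=80)])
        contigs = merge_contigs(pairs, "s", config)
        assert sum(c.read_count for c in contigs) <= len(pairs)


def _contig(start, end, reads, sample, strand="+"):
    return Contig(_iv(start, end, strand), [f"{sample}x{i}" for i in range(reads)], sample)


class TestConditionConsensus:
    def test_identical_contig_in_all_samples(self):
        per_sample = {s: [_contig(100, 140, 6, s)] for s in ("a", "b", "c")}
        (cons,) = condition_consensus(per_sample, "control")
        assert (cons.interval.start, cons.interval.end) == (100, 140)
        assert set(cons.per_sample_read_counts) == {"a", "b", "c"}

    def test_contig_absent_from_one_sample_drops_out(self):
        per_sample = {
            "a": [_contig(100, 140, 6, "a")],
            "b": [_contig(100, 140, 6, "b")],
            "c": [],
        }
        assert condition_consensus(per_sample, "control") == []

    def test_staggered_contigs_intersect_to_common_core(self):
        per_sample = {
            "a": [_contig(0, 30, 6, "a")],
            "b": [_contig(10, 40, 6, "b")],
            "c": [_contig(20, 50, 6, "c")],
        }
        (cons,) = condition_consensus(per_sample, "control")
        assert (cons.interval.start, cons.interval.end) == (20, 30)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            condition_consensus({}, "control")

    def test_matches_per_base_oracle(self, rng):
        for _ in range(40):
            per_sample = {}
            spans_by_sample = {}
            for s in ("a", "b", "c"):
                n = int(rng.integers(1, 8))
                spans = []
                for _i in range(n):
                    start = int(rng.integers(0, 150))
                    spans.append((start, start + int(rng.integers(10, 60))))
                spans_by_sample[s] = spans
                per_sample[s] = [
                    Contig(_iv(lo, hi), ["r"] * 5, s) for lo, hi in spans
                ]
            got = [
                (c.interval.start, c.interval.end)
                for c in condition_consensus(per_sample, "ctrl")
            ]
            assert got == brute_consensus(spans_by_sample, 260)

    def test_consensus_contained_in_every_sample_and_counts_from_intervals(self, rng):
        per_sample = {
            "a": [_contig(0, 50, 6, "a")],
            "b": [_contig(20, 80, 6, "b")],
        }
        intervals = {
            "a": _pairs([(0, 30), (25, 50), (30, 60)], prefix="a"),
            "b": _pairs([(20, 45), (100, 130)], prefix="b"),
        }
        (cons,) = condition_consensus(per_sample, "ctrl", intervals)
        for sample, contigs in per_sample.items():
            assert any(
                c.interval.start <= cons.interval.start and c.interval.end >= cons.interval.end
                for c in contigs
            )
        # counts recomputed over the consensus window [20, 50)
        assert cons.per_sample_read_counts == {"a": 3, "b": 1}
        assert all(n >= 1 for n in cons.per_sample_read_counts.values())


def test_unify_consensus_deduplicates_identical_intervals():
    from srnascan.contigs import ConsensusContig

    a = ConsensusContig(_iv(0, 50), "control", {"c1": 5})
    b = ConsensusContig(_iv(0, 50), "case", {"k1": 7})
    c = ConsensusContig(_iv(100, 160), "case", {"k1": 9})
    out = unify_consensus([[a], [b, c]])
    assert len(out) == 2
    merged = next(x for x in out if x.interval.start == 0)
    assert merged.per_sample_read_counts == {"c1": 5, "k1": 7}
    assert merged.condition == "control+case"
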