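"""Two-round alignment: contracts, symmetry, oracle agreement, SAM I/O."""

import numpy as np
import pytest

from _oracles import naive_map
from conftest import random_seq
from srnascan.aligner import (
    import_alignments,
    map_round1,
    map_round2,
    reverse_complement,
    write_sam,
)
from srnascan.config import PipelineConfig
from srnascan.preprocess import ReadRecord


def _reads(*seqs):
    return [ReadRecord(f"r{i}", s) for i, s in enumerate(seqs)]


class TestRound1:
    def test_unique_exact_match(self, rng):
        ref = {"ncrna1": random_seq(rng, 80)}
        read = ref["ncrna1"][10:32]
        result = map_round1(_reads(read), ref)
        (aln,) = result.alignments
        assert (aln.ref_id, aln.start, aln.end) == ("ncrna1", 10, 32)
        assert aln.n_hits == 1 and aln.mismatches == 0 and aln.round == 1

    def test_two_identical_references_give_two_hits(self, rng):
        seq = random_seq(rng, 60)
        ref = {"copyA": seq, "copyB": seq}
        result = map_round1(_reads(seq[5:27]), ref)
        assert len(result.alignments) == 2
        assert {a.ref_id for a in result.alignments} == {"copyA", "copyB"}
        assert all(a.n_hits == 2 for a in result.alignments)

    def test_mismatch_ratio_bound_is_exclusive(self, rng):
        # a 20-nt read with one central mismatch: 1/20 = 0.05 is NOT < 0.05,
        # and every clipped sub-match still contains the mismatch
        ref_seq = random_seq(rng, 20)
        read = ref_seq[:10] + ("A" if ref_seq[10] != "A" else "C") + ref_seq[11:]
        result = map_round1(_reads(read), {"ncrna1": ref_seq})
        assert result.alignments == []
        assert result.unmapped_read_ids == {"r0"}

    def test_soft_clip_rescues_terminal_mismatches(self, rng):
        ref_seq = random_seq(rng, 40)
        # mismatch at read position 20 of a 22-nt read: clipping to L=20 gives m=0
        read = ref_seq[:20] + ("A" if ref_seq[20] != "A" else "C") + ref_seq[21:22]
        result = map_round1(_reads(read), {"ncrna1": ref_seq})
        (aln,) = result.alignments
        assert aln.matched_len == 20 and aln.mismatches == 0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            map_round1(_reads("ACGT" * 6), {})


class TestRound2:
    def test_exact_end_to_end(self, rng):
        genome = {"chr1": random_seq(rng, 300)}
        read = genome["chr1"][100:130]
        result = map_round2(_reads(read), genome)
        (aln,) = result.alignments
        assert (aln.start, aln.end, aln.matched_len) == (100, 130, 30)

    def test_clipped_match_not_allowed(self, rng):
        genome = {"chr1": random_seq(rng, 200)}
        # last 3 nt mismatch: a 27-nt clipped match exists but not end-to-end
        core = genome["chr1"][50:77]
        bad_tail = "".join("A" if c != "A" else "C" for c in genome["chr1"][77:80])
        result = map_round2(_reads(core + bad_tail), genome)
        assert result.alignments == []
        assert result.unmapped_read_ids == {"r0"}

    def test_one_mismatch_in_44nt_is_below_ratio(self, rng):
        genome = {"chr1": random_seq(rng, 300)}
        read = list(genome["chr1"][30:74])
        read[20] = "A" if read[20] != "A" else "C"
        result = map_round2(_reads("".join(read)), genome)
        (aln,) = result.alignments
        assert aln.mismatches == 1 and aln.matched_len == 44  # 1/44 < 0.023


def test_reverse_complement_symmetry(rng):
    genome = {"chr1": random_seq(rng, 500)}
    read = genome["chr1"][200:240]
    fwd = map_round2(_reads(read), genome).alignments
    rev = map_round2(_reads(reverse_complement(read)), genome).alignments
    assert [(a.ref_id, a.start, a.end) for a in fwd] == [
        (a.ref_id, a.start, a.end) for a in rev
    ]
    assert {a.strand for a in fwd} == {"+"} and {a.strand for a in rev} == {"-"}


def test_round_disjointness(rng):
    ncrna = {"mir1": random_seq(rng, 22)}
    genome = {"chr1": random_seq(rng, 400) + ncrna["mir1"] + random_seq(rng, 50)}
    reads = _reads(ncrna["mir1"], genome["chr1"][100:140], "ACGT" * 8)
    r1 = map_round1(reads, ncrna)
    by_id = {r.read_id: r for r in reads}
    leftovers = [by_id[rid] for rid in sorted(r1.unmapped_read_ids)]
    r2 = map_round2(leftovers, genome)
    assert r1.mapped_read_ids & r2.mapped_read_ids == set()
    assert r1.mapped_read_ids | r2.mapped_read_ids | r2.unmapped_read_ids == {
        "r0", "r1", "r2"
    }


def _mutate(rng, seq, n_mut):
    out = list(seq)
    for pos in rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False):
        out[pos] = "ACGT"[(("ACGT".index(out[pos])) + 1 + int(rng.integers(3))) % 4]
    return "".join(out)


@pytest.mark.parametrize("round_no", [1, 2])
def test_oracle_equivalence_small(rng, round_no):
    """Seeded aligner equals the naive all-offsets scan on random instances."""
    cfg = PipelineConfig()
    for trial in range(15):
        refs = {
            f"ref{j}": random_seq(rng, int(rng.integers(60, 400))) for j in range(4)
        }
        reads = []
        for i in range(12):
            src = refs[f"ref{int(rng.integers(4))}"]
            length = int(rng.integers(16, min(50, len(src))))
            start = int(rng.integers(0, len(src) - length + 1))
            seq = _mutate(rng, src[start : start + length], int(rng.integers(0, 3)))
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            reads.append(ReadRecord(f"t{trial}r{i}", seq))
        if round_no == 1:
            result = map_round1(reads, refs, cfg)
            params = dict(min_match=cfg.round1_min_match, ratio=cfg.round1_mismatch_ratio,
                          end_to_end=False)
        else:
            result = map_round2(reads, refs, cfg)
            params = dict(min_match=cfg.round2_min_match, ratio=cfg.round2_mismatch_ratio,
                          end_to_end=True)
        got = {}
        for a in result.alignments:
            got.setdefault(a.read_id, []).append(
                (a.ref_id, a.start, a.end, a.strand, a.mismatches, a.matched_len)
            )
        for read in reads:
            expected = naive_map(read.sequence, refs, **params)
            if not expected or len(expected) > cfg.max_hits:
                assert read.read_id in result.unmapped_read_ids
            else:
                assert sorted(got[read.read_id]) == sorted(expected), read.read_id


class TestSamIO:
    def test_write_then_import_round_trip(self, rng, tmp_path):
        genome = {"chr1": random_seq(rng, 300)}
        seqs = {"r0": genome["chr1"][40:80], "r1": reverse_complement(genome["chr1"][100:140]),
                "r2": "ACGT" * 10}
        reads = [ReadRecord(k, v) for k, v in seqs.items()]
        result = map_round2(reads, genome)
        path = tmp_path / "out.sam"
        write_sam(result, genome, path, seqs)
        back = import_alignments(path, round_no=2)
        assert back.unmapped_read_ids == result.unmapped_read_ids
        assert sorted(
            (a.read_id, a.ref_id, a.start, a.end, a.strand, a.n_hits, a.matched_len)
            for a in back.alignments
        ) == sorted(
            (a.read_id, a.ref_id, a.start, a.end, a.strand, a.n_hits, a.matched_len)
            for a in result.alignments
        )

    def test_nh_tag_wins_over_record_tally(self, tmp_path, caplog):
        sam = tmp_path / "one.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "readA\t0\tchr1\t101\t255\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNH:i:3\tNM:i:0\n"
        )
        result = import_alignments(sam)
        (aln,) = result.alignments
        assert aln.n_hits == 3  # tag kept although only one record present

    def test_only_unmapped_records(self, tmp_path):
        sam = tmp_path / "un.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "readA\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGT\t*\n"
        )
        result = import_alignments(sam)
        assert result.alignments == [] and result.unmapped_read_ids == {"readA"}

    def test_two_records_tally_to_two_hits(self, tmp_path):
        sam = tmp_path / "two.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "readA\t0\tchr1\t101\t255\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNM:i:0\n"
            "readA\t0\tchr1\t301\t255\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNM:i:0\n"
        )
        result = import_alignments(sam)
        assert len(result.alignments) == 2
        assert all(a.n_hits == 2 for a in result.alignments)
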