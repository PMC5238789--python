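"""Counting, size factors, BH correction and the NB Wald test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_formula
from srnascan.aligner import AlignmentRecord
from srnascan.clustering import Feature
from srnascan.config import PipelineConfig
from srnascan.contigs import GenomicInterval
from srnascan.de import (
    CountMatrix,
    bh_adjust,
    count_features,
    nb_wald_test,
    size_factors,
)


def _known(fid, *ref_ids):
    return Feature(fid, "known", name=fid, ref_ids=ref_ids or (fid,))


def _novel(fid, start, end, strand="+"):
    return Feature(fid, "novel", interval=GenomicInterval("chr1", start, end, strand))


def _aln(read_id, ref, start, end, round_no, strand="+", n_hits=1):
    return AlignmentRecord(read_id, ref, start, end, strand, 0, end - start, n_hits, round_no)


class TestCountFeatures:
    def test_zero_when_no_overlap(self):
        cm = count_features(
            [_novel("nv", 100, 150)], {"s1": [_aln("r", "chr1", 500, 530, 2)]}
        )
        assert cm.counts[0, 0] == 0

    def test_seven_overlapping_alignments(self):
        alns = [_aln(f"r{i}", "chr1", 100 + i, 130 + i, 2) for i in range(7)]
        cm = count_features([_novel("nv", 100, 150)], {"s1": alns})
        assert cm.counts[0, 0] == 7

    def test_identical_spans_all_counted(self):
        alns = [_aln(f"r{i}", "chr1", 100, 130, 2) for i in range(5)]
        cm = count_features([_novel("nv", 90, 140)], {"s1": alns})
        assert cm.counts[0, 0] == 5

    def test_multimapped_read_adds_to_each_feature(self):
        alns = [
            _aln("mm", "chr1", 100, 130, 2, n_hits=2),
            _aln("mm", "chr1", 500, 530, 2, n_hits=2),
        ]
        cm = count_features([_novel("a", 90, 140), _novel("b", 490, 540)], {"s1": alns})
        assert cm.counts[:, 0].tolist() == [1, 1]

    def test_known_features_sum_over_duplicate_reference_entries(self):
        feats = [_known("mir-1", "mir-1|a", "mir-1|b")]
        alns = [_aln("r1", "mir-1|a", 0, 22, 1), _aln("r2", "mir-1|b", 0, 22, 1)]
        cm = count_features(feats, {"s1": alns})
        assert cm.counts[0, 0] == 2

    def test_strandedness_of_novel_counting(self):
        alns = [_aln("r", "chr1", 100, 130, 2, strand="-")]
        cm = count_features([_novel("plus", 90, 140, "+")], {"s1": alns})
        assert cm.counts[0, 0] == 0


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        mat = np.array([[10, 10], [20, 20], [7, 7]])
        assert size_factors(mat) == pytest.approx([1.0, 1.0])

    def test_doubled_sample_proportional_to_two(self):
        mat = np.array([[10, 20], [30, 60], [7, 14]])
        f = size_factors(mat)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_median_of_ratios_worked_example(self):
        mat = np.array([[10, 20, 10], [20, 40, 20], [30, 60, 30]])
        f = size_factors(mat)
        assert f / f[0] == pytest.approx([1.0, 2.0, 1.0])

    def test_scale_equivariance_up_to_normalization(self, rng):
        # factors are defined relative to the geometric-mean reference, so
        # scaling one sample by c multiplies its factor by c *relative to*
        # the other samples' factors
        mat = rng.integers(1, 500, size=(60, 5))
        f0 = size_factors(mat)
        scaled = mat.copy()
        scaled[:, 2] *= 3
        f1 = size_factors(scaled)
        assert (f1[2] / f1[0]) / (f0[2] / f0[0]) == pytest.approx(3.0, rel=1e-9)
        assert (f1[4] / f1[0]) / (f0[4] / f0[0]) == pytest.approx(1.0, rel=1e-9)

    def test_no_common_feature_errors_and_pseudo_reference_fallback(self):
        mat = np.array([[5, 0], [0, 7]])
        with pytest.raises(ValueError, match="allow_pseudo_reference"):
            size_factors(mat)
        f = size_factors(np.array([[5, 0, 5], [0, 7, 7], [3, 3, 3]]),
                         allow_pseudo_reference=True)
        assert np.all(f > 0)


class TestBHAdjust:
    def test_single_pvalue_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=150, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_closed_form_and_is_monotone(self, pvals):
        adj = bh_adjust(pvals)
        assert adj == pytest.approx(bh_formula(pvals))
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(25):
            p = rng.random(int(rng.integers(1, 200)))
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            assert bh_adjust(p) == pytest.approx(expected)


def _nb(rng, mean, disp, size):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mean), size=size)


class TestNBWaldTest:
    def _matrix(self, counts, n_ctl, n_case):
        samples = [f"c{i}" for i in range(n_ctl)] + [f"k{i}" for i in range(n_case)]
        condition = {s: ("control" if s.startswith("c") else "case") for s in samples}
        features = [f"f{i}" for i in range(counts.shape[0])]
        return CountMatrix(features, samples, counts, condition)

    def test_identical_groups_give_zero_lfc_and_unit_pvalue(self):
        counts = np.tile([[50], [200]], (1, 8))
        cm = self._matrix(counts, 4, 4)
        results = nb_wald_test(cm)
        for r in results:
            assert r.log2fc == pytest.approx(0.0)
            assert r.pvalue == pytest.approx(1.0)
            assert not r.significant

    def test_all_zero_feature_excluded(self, rng):
        counts = np.vstack([_nb(rng, 50, 0.1, 8), np.zeros(8, dtype=int)])
        cm = self._matrix(counts, 4, 4)
        results = nb_wald_test(cm)
        assert results[1].padj is None and not results[1].significant

    def test_recovers_200_fold_decrease(self, rng):
        # focal feature: control mean 2000 vs case mean 10, dispersion 0.1
        n_ctl, n_case = 10, 15
        rows = [np.concatenate([_nb(rng, 2000, 0.1, n_ctl), _nb(rng, 10, 0.1, n_case)])]
        for _ in range(60):
            mean = float(rng.uniform(20, 300))
            rows.append(_nb(rng, mean, 0.1, n_ctl + n_case))
        cm = self._matrix(np.vstack(rows), n_ctl, n_case)
        focal = nb_wald_test(cm)[0]
        assert focal.significant
        assert abs(focal.log2fc) == pytest.approx(math.log2(200), abs=1.0)
        assert focal.log2fc < 0

    def test_too_few_samples_rejected(self):
        counts = np.array([[5, 6, 7]])
        cm = CountMatrix(["f"], ["a", "b", "c"],
                         counts, {"a": "control", "b": "control", "c": "case"})
        with pytest.raises(ValueError, match="at least 2"):
            nb_wald_test(cm)

    def test_significance_uses_strict_threshold(self, rng):
        cfg = PipelineConfig()
        counts = np.vstack([_nb(rng, 100, 0.05, 12) for _ in range(30)])
        counts[0, 6:] *= 8  # one strong effect
        cm = self._matrix(counts, 6, 6)
        for r in nb_wald_test(cm, config=cfg):
            assert r.significant == (r.padj is not None and r.padj < cfg.padj_threshold)
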