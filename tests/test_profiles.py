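"""Class abundance, positional profiles, fragment calls, DE summaries, PCA."""

import numpy as np
import pytest

from srnascan.aligner import AlignmentRecord
from srnascan.annotation import AnnotatedFeature
from srnascan.de import CountMatrix, DEResult, size_factors
from srnascan.profiles import (
    class_abundance,
    classify_fragment,
    de_summary,
    positional_profile,
    report_matrices,
)


def _annotated(fid, cls, name="x"):
    return AnnotatedFeature(fid, fid, None if cls == "novel" else name, cls)


def _cm(features, counts, n_samples=2):
    samples = [f"s{i}" for i in range(n_samples)]
    condition = {s: "control" for s in samples}
    return CountMatrix(features, samples, counts, condition)


class TestClassAbundance:
    def test_all_reads_on_mirna(self):
        cm = _cm(["a", "b"], np.array([[10, 10], [5, 5]]))
        ab = class_abundance([_annotated("a", "miRNA"), _annotated("b", "miRNA")], cm)
        assert ab.read_fractions == {"miRNA": pytest.approx(1.0)}
        assert ab.feature_counts == {"miRNA": 2}

    def test_fractions_against_stated_total(self):
        cm = _cm(["mi", "t", "sno"], np.array([[78], [6], [2]]), n_samples=1)
        annotated = [_annotated("mi", "miRNA"), _annotated("t", "tRNA"),
                     _annotated("sno", "snoRNA")]
        ab = class_abundance(annotated, cm, total_mapped_reads=100)
        assert ab.read_fractions == {
            "miRNA": pytest.approx(0.78),
            "tRNA": pytest.approx(0.06),
            "snoRNA": pytest.approx(0.02),
        }
        assert sum(ab.read_fractions.values()) <= 1.0

    def test_empty_matrix(self):
        cm = _cm([], np.zeros((0, 2), dtype=int))
        ab = class_abundance([], cm)
        assert sum(ab.read_fractions.values()) == 0.0

    def test_matches_per_read_tally(self, rng):
        n = 12
        counts = rng.integers(0, 50, size=(n, 3))
        classes = rng.choice(["miRNA", "tRNA", "novel"], size=n)
        cm = _cm([f"f{i}" for i in range(n)], counts, 3)
        annotated = [_annotated(f"f{i}", c) for i, c in enumerate(classes)]
        ab = class_abundance(annotated, cm)
        total = counts.sum()
        for cls in set(classes):
            expected = counts[classes == cls].sum() / total
            assert ab.read_fractions[cls] == pytest.approx(expected)


def _aln(ref, start, end, strand="+"):
    return AlignmentRecord("r", ref, start, end, strand, 0, end - start, 1, 1)


class TestPositionalProfile:
    def test_five_prime_fragments_mass_at_offset_zero(self, rng):
        alns = [_aln("trna1", 0, int(rng.integers(32, 37))) for _ in range(50)]
        prof = positional_profile("trna1", {"s1": alns}, 72)
        assert set(prof.start_offset_histogram) == {0}
        assert set(prof.raw_length_histogram) <= set(range(32, 37))
        assert prof.fragment_call == "five_prime_fragment"

    def test_full_length_mt_trna(self):
        alns = [_aln("mt1", 0, 65) for _ in range(30)]
        prof = positional_profile("mt1", {"s1": alns}, 65)
        assert prof.raw_length_histogram == {65: 30}
        assert prof.fragment_call == "full_length"

    def test_no_reads_gives_empty_histograms(self):
        prof = positional_profile("f", {"s1": []}, 72)
        assert prof.raw_length_histogram == {} and prof.fragment_call == "mixed"

    def test_mass_conservation(self, rng):
        alns = []
        for _ in range(40):
            start = int(rng.integers(0, 40))
            alns.append(_aln("f", start, start + int(rng.integers(16, 30))))
        prof = positional_profile("f", {"s1": alns[:25], "s2": alns[25:]}, 80)
        assert sum(prof.start_offset_histogram.values()) == 40
        assert sum(prof.raw_length_histogram.values()) == 40
        assert prof.n_alignments == 40

    def test_minus_strand_offsets_in_feature_orientation(self):
        # a read covering the last 30 nt of a 72-nt feature on '-' starts at
        # feature-5'-offset 42 when measured in feature orientation? no:
        # for '-' alignments the feature 5' end is the interval's high end
        prof = positional_profile("f", {"s": [_aln("f", 42, 72, "-")]}, 72)
        assert prof.start_offset_histogram == {0: 1}

    def test_normalized_mean_uses_size_factors(self):
        alns = {"a": [_aln("f", 0, 22)] * 4, "b": [_aln("f", 0, 22)] * 8}
        prof = positional_profile(
            "f", alns, 22, {"a": "control", "b": "control"}, {"a": 1.0, "b": 2.0}
        )
        assert prof.length_histogram["control"][22] == pytest.approx(4.0)

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            positional_profile("f", {"s": []}, 0)


class TestClassifyFragment:
    def test_uniform_starts_and_lengths_are_mixed(self, rng):
        alns = []
        for _ in range(200):
            start = int(rng.integers(0, 50))
            length = int(rng.integers(16, 72 - start))
            alns.append(_aln("f", start, start + length))
        prof = positional_profile("f", {"s": alns}, 72)
        assert prof.fragment_call in ("mixed", "internal")

    def test_three_prime_fragment(self):
        alns = [_aln("f", 72 - L, 72) for L in (30, 32, 33, 34, 31) for _ in range(5)]
        prof = positional_profile("f", {"s": alns}, 72)
        assert prof.fragment_call == "three_prime_fragment"

    def test_internal_fragments(self):
        alns = [_aln("f", 20, 38) for _ in range(30)]
        prof = positional_profile("f", {"s": alns}, 72)
        assert prof.fragment_call == "internal"


def _de(fid, lfc, padj):
    return DEResult(fid, 10.0, lfc, 0.5, lfc / 0.5, 0.01, padj, padj is not None and padj < 0.1)


class TestDESummary:
    def test_single_contrast_counts(self):
        res = [_de("a", 2.0, 0.01), _de("b", -1.0, 0.05), _de("c", 1.0, 0.02),
               _de("d", 1.0, 0.5)]
        summary, overlap = de_summary({"I_vs_control": res})
        row = summary.iloc[0]
        assert (row.n_significant, row.n_up, row.n_down) == (3, 2, 1)
        assert overlap == {"a", "b", "c"}

    def test_intersection_across_contrasts(self):
        contrasts = {
            "I": [_de(x, 1.0, 0.01) for x in "abc"],
            "II": [_de(x, 1.0, 0.01) for x in "bc"],
            "III": [_de(x, 1.0, 0.01) for x in "bcd"],
        }
        _, overlap = de_summary(contrasts)
        assert overlap == {"b", "c"}

    def test_empty_significant_sets(self):
        contrasts = {"I": [_de("a", 1.0, 0.9)], "II": [_de("a", 1.0, 0.8)]}
        _, overlap = de_summary(contrasts)
        assert overlap == set()

    def test_no_contrasts_rejected(self):
        with pytest.raises(ValueError):
            de_summary({})


class TestReportMatrices:
    def test_identical_samples_coincide_in_pca(self, rng):
        base = rng.integers(0, 200, size=(20, 1))
        counts = np.hstack([base, base, rng.integers(0, 200, size=(20, 1))])
        cm = _cm([f"f{i}" for i in range(20)], counts, 3)
        _, pca, evr = report_matrices(cm, size_factors(cm, allow_pseudo_reference=True),
                                      [])
        assert pca.loc["s0", ["PC1", "PC2"]].to_numpy() == pytest.approx(
            pca.loc["s1", ["PC1", "PC2"]].to_numpy(), abs=1e-9
        )
        assert evr.sum() <= 1.0 + 1e-9

    def test_heatmap_rows_centered(self, rng):
        counts = rng.integers(1, 300, size=(15, 6))
        cm = _cm([f"f{i}" for i in range(15)], counts, 6)
        heat, _, _ = report_matrices(cm, np.ones(6), [f"f{i}" for i in range(5)])
        assert heat.shape[0] == 5
        assert np.allclose(heat.sum(axis=1), 0.0, atol=1e-9)

    def test_constant_matrix_rejected(self):
        cm = _cm(["a", "b"], np.full((2, 3), 7), 3)
        with pytest.raises(ValueError, match="non-constant"):
            report_matrices(cm, np.ones(3), [])
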