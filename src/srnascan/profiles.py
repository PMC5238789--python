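"""Class-abundance accounting, tRF/mt-tRNA positional profiles, DE summaries.

tRNA halves produced by anticodon-loop cleavage are 30-36 nt and start at the
5' end of the parent tRNA; D-/T-stem cleavage yields 13-20 nt fragments;
mitochondrial tRNAs (60-68 nt) tend to appear full length.  The positional
profile of a feature therefore records a read-length histogram (normalized
mean reads per condition) and 5'-offset/3'-offset histograms, from which a
qualitative fragment call is derived: a feature whose reads overwhelmingly
start within the first 3 nt and whose modal read length sits well inside the
parent is a 5' fragment; a modal length within 5 nt of the parent length is
full length.  The 80% concentration threshold, 3-nt window and modal-length
bands are configurable conventions that make the qualitative contrast
computable.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aligner import AlignmentRecord
from .annotation import AnnotatedFeature
from .de import CountMatrix, DEResult

__all__ = [
    "ClassAbundance",
    "FeatureProfile",
    "FragmentRule",
    "class_abundance",
    "positional_profile",
    "classify_fragment",
    "de_summary",
    "report_matrices",
    "write_class_abundance_tsv",
    "write_profile_tsv",
]


@dataclass
class ClassAbundance:
    read_fractions: dict[str, float]
    feature_counts: dict[str, int]
    total_reads: int


@dataclass(frozen=True)
class FragmentRule:
    """Thresholds behind the qualitative fragment call."""

    start_concentration: float = 0.8
    start_window: int = 3  # reads 'start at the 5'' when offset < start_window
    min_fragment_len: int = 25
    end_margin: int = 10  # fragment modal length <= parent length - end_margin
    full_length_margin: int = 5


@dataclass
class FeatureProfile:
    feature_id: str
    feature_length: int
    # condition -> {read length -> normalized mean reads}
    length_histogram: dict[str, dict[int, float]]
    start_offset_histogram: dict[int, int]
    end_offset_histogram: dict[int, int]  # offset measured back from the 3' end
    raw_length_histogram: dict[int, int]
    n_alignments: int
    fragment_call: str = "mixed"


def class_abundance(
    annotated: list[AnnotatedFeature],
    counts: CountMatrix,
    total_mapped_reads: int | None = None,
) -> ClassAbundance:
    """Per-class mapped-read fractions and unique-feature counts.

    ``total_mapped_reads`` defaults to the grand total of the count matrix;
    passing the pipeline's true mapped-read total leaves room for an
    unannotated remainder, so fractions sum to <= 1.
    """
    class_of = {af.feature_id: af.assigned_class for af in annotated}
    totals = counts.counts.sum(axis=1)
    reads_per_class: Counter = Counter()
    features_per_class: Counter = Counter()
    for i, fid in enumerate(counts.features):
        cls = class_of.get(fid, "novel")
        reads_per_class[cls] += int(totals[i])
        features_per_class[cls] += 1
    total = total_mapped_reads if total_mapped_reads is not None else int(totals.sum())
    fractions = {
        cls: (reads_per_class[cls] / total if total > 0 else 0.0)
        for cls in sorted(reads_per_class)
    }
    return ClassAbundance(fractions, dict(sorted(features_per_class.items())), total)


def _offsets(aln: AlignmentRecord, feature_length: int) -> tuple[int, int]:
    """(5' offset, 3' offset) of an alignment in feature orientation."""
    if aln.strand == "+":
        return aln.start, feature_length - aln.end
    return feature_length - aln.end, aln.start


def positional_profile(
    feature_id: str,
    alignments_by_sample: dict[str, list[AlignmentRecord]],
    feature_length: int,
    condition: dict[str, str] | None = None,
    sample_size_factors: dict[str, float] | None = None,
    rule: FragmentRule | None = None,
) -> FeatureProfile:
    """Length and positional histograms of the reads covering one feature.

    Offsets are measured from the feature's 5' end in feature orientation.
    The length histogram is reported per condition as the mean over samples of
    size-factor-normalized read counts ('normalized mean reads'); raw
    histograms (total mass = number of alignments) feed the fragment call.
    """
    if feature_length <= 0:
        raise ValueError("feature_length must be positive")
    cond = condition or {}
    sfs = sample_size_factors or {}
    per_condition: dict[str, dict[str, Counter]] = {}
    start_hist: Counter = Counter()
    end_hist: Counter = Counter()
    raw_len: Counter = Counter()
    n_alignments = 0
    for sample, alignments in sorted(alignments_by_sample.items()):
        level = cond.get(sample, "all")
        sample_lengths: Counter = Counter()
        for aln in alignments:
            length = aln.end - aln.start
            off5, off3 = _offsets(aln, feature_length)
            start_hist[off5] += 1
            end_hist[off3] += 1
            raw_len[length] += 1
            sample_lengths[length] += 1
            n_alignments += 1
        per_condition.setdefault(level, {})[sample] = sample_lengths
    length_histogram: dict[str, dict[int, float]] = {}
    for level, by_sample in sorted(per_condition.items()):
        lengths = sorted({ln for c in by_sample.values() for ln in c})
        hist = {}
        for ln in lengths:
            values = [c[ln] / sfs.get(s, 1.0) for s, c in sorted(by_sample.items())]
            hist[ln] = float(np.mean(values))
        length_histogram[level] = hist
    profile = FeatureProfile(
        feature_id=feature_id,
        feature_length=feature_length,
        length_histogram=length_histogram,
        start_offset_histogram=dict(sorted(start_hist.items())),
        end_offset_histogram=dict(sorted(end_hist.items())),
        raw_length_histogram=dict(sorted(raw_len.items())),
        n_alignments=n_alignments,
    )
    profile.fragment_call = classify_fragment(profile, feature_length, rule)
    return profile


def classify_fragment(
    profile: FeatureProfile, feature_length: int, rule: FragmentRule | None = None
) -> str:
    """Qualitative fragment call from a feature's positional profile.

    Returns one of ``five_prime_fragment``, ``three_prime_fragment``,
    ``full_length``, ``internal`` or ``mixed``.
    """
    r = rule or FragmentRule()
    total = sum(profile.start_offset_histogram.values())
    if total == 0:
        return "mixed"
    frac_start_5p = (
        sum(n for off, n in profile.start_offset_histogram.items() if off < r.start_window)
        / total
    )
    frac_end_3p = (
        sum(n for off, n in profile.end_offset_histogram.items() if off < r.start_window)
        / total
    )
    modal_length = max(
        profile.raw_length_histogram, key=lambda ln: (profile.raw_length_histogram[ln], ln)
    )
    fragment_band = (
        r.min_fragment_len <= modal_length <= feature_length - r.end_margin
    )
    if frac_start_5p >= r.start_concentration and fragment_band:
        return "five_prime_fragment"
    if frac_end_3p >= r.start_concentration and fragment_band:
        return "three_prime_fragment"
    if modal_length >= feature_length - r.full_length_margin:
        return "full_length"
    frac_internal_start = 1.0 - sum(
        n for off, n in profile.start_offset_histogram.items() if off < r.start_window
    ) / total
    frac_internal_end = 1.0 - sum(
        n for off, n in profile.end_offset_histogram.items() if off < r.start_window
    ) / total
    if frac_internal_start >= r.start_concentration and frac_internal_end >= r.start_concentration:
        return "internal"
    return "mixed"


def de_summary(
    per_contrast: dict[str, list[DEResult]],
    overlap_contrasts: list[str] | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Per-contrast significant tallies (split by fold-change sign) and the
    intersection of significant feature-id sets over ``overlap_contrasts``
    (default: all contrasts)."""
    if not per_contrast:
        raise ValueError("at least one contrast required")
    rows = []
    sig_sets: dict[str, set[str]] = {}
    for name, results in per_contrast.items():
        sig = [r for r in results if r.significant]
        sig_sets[name] = {r.feature_id for r in sig}
        rows.append(
            {
                "contrast": name,
                "n_significant": len(sig),
                "n_up": sum(1 for r in sig if r.log2fc > 0),
                "n_down": sum(1 for r in sig if r.log2fc < 0),
            }
        )
    wanted = overlap_contrasts if overlap_contrasts is not None else sorted(per_contrast)
    overlap: set[str] | None = None
    for name in wanted:
        overlap = sig_sets[name] if overlap is None else (overlap & sig_sets[name])
    return pd.DataFrame(rows), (overlap or set())


def report_matrices(
    counts: CountMatrix,
    factors: np.ndarray,
    significant_features: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Plot-ready heatmap matrix and sample PCA coordinates.

    The heatmap matrix is log2(normalized count + 1), restricted to the
    significant features and row-centered.  The PCA runs on the full
    transformed matrix with samples as points; the top two components and
    their explained-variance fractions are returned.
    """
    from sklearn.decomposition import PCA

    if len(counts.samples) < 2:
        raise ValueError("at least 2 samples required")
    norm = counts.counts / np.asarray(factors)
    logmat = np.log2(norm + 1.0)
    frame = pd.DataFrame(logmat, index=counts.features, columns=counts.samples)
    heat = frame.loc[[f for f in significant_features if f in frame.index]]
    heatmap = heat.sub(heat.mean(axis=1), axis=0)
    non_constant = int((frame.std(axis=1) > 0).sum())
    if non_constant < 2:
        raise ValueError("PCA requires at least 2 non-constant features")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(logmat.T)
    pca_frame = pd.DataFrame(coords, index=counts.samples, columns=["PC1", "PC2"])
    pca_frame["condition"] = [counts.condition.get(s, "") for s in counts.samples]
    return heatmap, pca_frame, pca.explained_variance_ratio_


def write_class_abundance_tsv(abundance: ClassAbundance, path: str | Path) -> None:
    classes = sorted(set(abundance.read_fractions) | set(abundance.feature_counts))
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["class", "read_fraction", "unique_features"])
        for cls in classes:
            writer.writerow(
                [cls, f"{abundance.read_fractions.get(cls, 0.0):.6f}",
                 abundance.feature_counts.get(cls, 0)]
            )


def write_profile_tsv(profiles: list[FeatureProfile], path: str | Path) -> None:
    """Long-format per-feature length profile (feature, condition, length, mean_reads)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["feature_id", "fragment_call", "condition", "read_length", "mean_reads"])
        for prof in profiles:
            for level, hist in sorted(prof.length_histogram.items()):
                for length, mean_reads in sorted(hist.items()):
                    writer.writerow(
                        [prof.feature_id, prof.fragment_call, level, length,
                         f"{mean_reads:.6g}"]
                    )
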