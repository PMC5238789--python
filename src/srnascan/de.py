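"""Counting and negative-binomial differential abundance.

Counts are modelled as NB with variance mu + alpha*mu^2.  Per-sample library
depth is normalized away with median-of-ratios size factors; per-feature
dispersions are estimated by method of moments, stabilised against a fitted
mean-dispersion trend (alpha0 + alpha1/mu, the maximum of gene-wise and
trended values is kept as a conservative shrinkage surrogate); log2 fold
changes come from normalized group means with a 0.5 pseudo-count safeguard,
and a Wald statistic with a delta-method standard error gives a two-sided
normal p-value, BH-adjusted across features.  This is a deliberately
simplified DESeq2-like stage: no Cox-Reid adjusted profile likelihood, no MAP
fold-change shrinkage, no independent filtering — its contract is statistical
behaviour (FDR control and effect recovery), verified by simulation.

Significance uses the strict inequality padj < threshold (default 0.1).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import optimize, stats

from .aligner import AlignmentRecord
from .clustering import Feature
from .config import PipelineConfig

__all__ = [
    "CountMatrix",
    "DEResult",
    "count_features",
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "write_counts_tsv",
    "write_de_tsv",
    "de_results_to_frame",
]

_DISPERSION_FLOOR = 1e-8
_PSEUDO = 0.5


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-sample condition labels."""

    features: list[str]
    samples: list[str]
    counts: np.ndarray
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if self.counts.size and (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.features, columns=self.samples)

    def samples_of(self, level: str) -> list[str]:
        return [s for s in self.samples if self.condition.get(s) == level]


@dataclass
class DEResult:
    feature_id: str
    base_mean: float
    log2fc: float
    se: float
    wald_stat: float
    pvalue: float
    padj: float | None
    significant: bool


def count_features(
    feature_set: list[Feature],
    per_sample_alignments: dict[str, list[AlignmentRecord]],
    condition: dict[str, str] | None = None,
) -> CountMatrix:
    """Count per-sample alignments over the final feature set.

    Known features are counted by reference-sequence id match on round-1
    records (summing over duplicated reference entries); novel features by
    same-strand genomic overlap of at least one base with round-2 records.
    Every alignment record counts, so a k-fold multimapped read adds one to
    each feature it overlaps.
    """
    samples = sorted(per_sample_alignments)
    counts = np.zeros((len(feature_set), len(samples)), dtype=np.int64)
    ref_index: dict[str, list[int]] = {}
    novel: list[tuple[int, Feature]] = []
    for i, feat in enumerate(feature_set):
        if feat.kind == "known":
            for rid in feat.ref_ids:
                ref_index.setdefault(rid, []).append(i)
        else:
            novel.append((i, feat))
    for j, sample in enumerate(samples):
        # identical alignment spans are frequent; count multiplicities per span
        spans: dict[tuple[str, str], dict[tuple[int, int], int]] = {}
        for aln in per_sample_alignments[sample]:
            if aln.round == 1:
                for i in ref_index.get(aln.ref_id, ()):
                    counts[i, j] += 1
            else:
                group = spans.setdefault((aln.ref_id, aln.strand), {})
                key = (aln.start, aln.end)
                group[key] = group.get(key, 0) + 1
        trees: dict[tuple[str, str], IntervalTree] = {}
        for group_key, multiplicities in spans.items():
            tree = IntervalTree()
            for (start, end), n in multiplicities.items():
                tree.addi(start, end, n)
            trees[group_key] = tree
        for i, feat in novel:
            iv = feat.interval
            tree = trees.get((iv.ref_id, iv.strand))
            if tree is not None:
                counts[i, j] += sum(hit.data for hit in tree.overlap(iv.start, iv.end))
    return CountMatrix(
        [f.feature_id for f in feature_set], samples, counts, dict(condition or {})
    )


def size_factors(
    counts: np.ndarray | CountMatrix, allow_pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios per-sample normalization factors.

    For each feature with nonzero counts in every sample, the ratio of each
    sample's count to the feature's geometric mean is formed; a sample's
    factor is the median of its ratios.  When no feature is nonzero
    everywhere, ``allow_pseudo_reference=True`` switches to a positive-count
    geometric mean with the median taken over each sample's positive counts.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValueError("counts must be a features x samples matrix")
    mat = mat.astype(float)
    all_positive = (mat > 0).all(axis=1)
    if all_positive.any():
        sub = mat[all_positive]
        log_geo = np.log(sub).mean(axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    elif allow_pseudo_reference:
        positive = mat > 0
        usable = positive.sum(axis=1) >= max(2, mat.shape[1] // 2)
        if not usable.any():
            raise ValueError("no feature has enough positive counts for normalization")
        sub = mat[usable]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        log_geo = np.nanmean(logs, axis=1, keepdims=True)
        ratios = logs - log_geo
        factors = np.exp(np.nanmedian(ratios, axis=0))
    else:
        raise ValueError(
            "no feature is nonzero in all samples; rerun with "
            "allow_pseudo_reference=True to use a positive-count pseudo-reference"
        )
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValueError("size factor estimation produced non-positive factors")
    return factors


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _fit_dispersion_trend(means: np.ndarray, alphas: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mean with non-negative coefficients."""
    ok = (means > 0) & np.isfinite(alphas)
    if ok.sum() < 2:
        med = float(np.median(alphas[ok])) if ok.any() else _DISPERSION_FLOOR
        return max(med, _DISPERSION_FLOOR), 0.0
    design = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, _ = optimize.nnls(design, alphas[ok])
    a0, a1 = float(coef[0]), float(coef[1])
    if a0 <= 0 and a1 <= 0:
        a0 = max(float(np.median(alphas[ok])), _DISPERSION_FLOOR)
    return a0, a1


def nb_wald_test(
    counts: CountMatrix,
    contrast: tuple[str, str] = ("case", "control"),
    config: PipelineConfig | None = None,
) -> list[DEResult]:
    """Per-feature NB Wald test of ``contrast[0]`` versus ``contrast[1]``.

    Features with all-zero counts across the compared samples are excluded
    from testing and reported with ``padj=None``.
    """
    cfg = config or PipelineConfig()
    case_level, control_level = contrast
    case = counts.samples_of(case_level)
    control = counts.samples_of(control_level)
    for level, group in ((case_level, case), (control_level, control)):
        if len(group) < 2:
            raise ValueError(f"condition {level!r} has {len(group)} samples; at least 2 required")
    cols = [counts.samples.index(s) for s in control + case]
    mat = counts.counts[:, cols].astype(float)
    n_ctl = len(control)
    sf = size_factors(mat.astype(np.int64), allow_pseudo_reference=True)
    q = mat / sf
    tested = mat.sum(axis=1) > 0

    mu_all = q.mean(axis=1)
    groups = [np.arange(n_ctl), np.arange(n_ctl, mat.shape[1])]
    inv_sf_mean = [float(np.mean(1.0 / sf[g])) for g in groups]
    # pooled within-group variance, then method-of-moments dispersion
    var_pooled = np.zeros(mat.shape[0])
    dof = sum(len(g) - 1 for g in groups)
    for g in groups:
        var_pooled += q[:, g].var(axis=1, ddof=1) * (len(g) - 1)
    var_pooled /= dof
    mean_inv_sf = float(np.mean(1.0 / sf))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gene = (var_pooled - mu_all * mean_inv_sf) / np.square(mu_all)
    alpha_gene = np.where(np.isfinite(alpha_gene), alpha_gene, _DISPERSION_FLOOR)
    alpha_gene = np.maximum(alpha_gene, _DISPERSION_FLOOR)
    a0, a1 = _fit_dispersion_trend(mu_all[tested], alpha_gene[tested])
    with np.errstate(divide="ignore"):
        alpha_trend = a0 + a1 / np.where(mu_all > 0, mu_all, np.inf)
    alpha = np.maximum(alpha_gene, alpha_trend)

    mu_ctl = q[:, groups[0]].mean(axis=1)
    mu_case = q[:, groups[1]].mean(axis=1)
    log2fc = np.log2((mu_case + _PSEUDO) / (mu_ctl + _PSEUDO))
    var_mean_ctl = (mu_ctl * inv_sf_mean[0] + alpha * np.square(mu_ctl)) / len(groups[0])
    var_mean_case = (mu_case * inv_sf_mean[1] + alpha * np.square(mu_case)) / len(groups[1])
    ln2sq = math.log(2) ** 2
    var_lfc = (
        var_mean_ctl / (np.square(mu_ctl + _PSEUDO) * ln2sq)
        + var_mean_case / (np.square(mu_case + _PSEUDO) * ln2sq)
    )
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    padj_sub = bh_adjust(pvals[tested])
    padj = np.full(mat.shape[0], np.nan)
    padj[tested] = padj_sub

    results: list[DEResult] = []
    for i, fid in enumerate(counts.features):
        if tested[i]:
            adj = float(padj[i])
            results.append(
                DEResult(
                    feature_id=fid,
                    base_mean=float(mu_all[i]),
                    log2fc=float(log2fc[i]),
                    se=float(se[i]),
                    wald_stat=float(wald[i]),
                    pvalue=float(pvals[i]),
                    padj=adj,
                    significant=adj < cfg.padj_threshold,
                )
            )
        else:
            results.append(
                DEResult(fid, 0.0, 0.0, float("nan"), float("nan"), float("nan"), None, False)
            )
    return results


def de_results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "base_mean": [r.base_mean for r in results],
            "log2fc": [r.log2fc for r in results],
            "se": [r.se for r in results],
            "wald_stat": [r.wald_stat for r in results],
            "pvalue": [r.pvalue for r in results],
            "padj": [np.nan if r.padj is None else r.padj for r in results],
            "significant": [r.significant for r in results],
        }
    )


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["feature_id", *cm.samples])
        for i, fid in enumerate(cm.features):
            writer.writerow([fid, *cm.counts[i].tolist()])


def write_de_tsv(results: list[DEResult], path: str | Path) -> None:
    frame = de_results_to_frame(results)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
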