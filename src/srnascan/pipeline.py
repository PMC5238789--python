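"""End-to-end orchestration of the discovery pipeline.

Stage order: preprocess -> round-1 mapping (custom ncRNA reference) ->
round-2 mapping (genome, round-1 leftovers only) -> per-sample contig
assembly -> per-condition consensus -> representative-contig clustering ->
feature-set assembly and annotation -> counting -> NB differential abundance
(each non-control level versus control) -> class abundance, tRF profiles and
report matrices.  A manifest records the parameter snapshot, seeds and
per-stage tallies and is rewritten atomically at each stage boundary, so a
run directory always describes itself.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .aligner import AlignmentRecord, MappingResult, import_alignments, map_round1, map_round2
from .annotation import (
    AnnotatedFeature,
    AnnotationRecord,
    annotate_features,
    classify_round1_feature,
    read_annotation_bed,
    read_annotation_gtf,
    write_annotated_tsv,
)
from .clustering import (
    Cluster,
    Feature,
    KnownFeature,
    assemble_feature_set,
    cluster_contigs,
    write_clusters_tsv,
)
from .config import PipelineConfig, load_config
from .contigs import (
    Contig,
    ConsensusContig,
    alignments_to_intervals,
    condition_consensus,
    merge_contigs,
    unify_consensus,
    write_consensus_tsv,
    write_contigs_bed,
)
from .de import (
    CountMatrix,
    DEResult,
    count_features,
    de_results_to_frame,
    nb_wald_test,
    size_factors,
    write_counts_tsv,
    write_de_tsv,
)
from .preprocess import ReadRecord, TrimReport, preprocess_reads, read_fastq
from .profiles import (
    FeatureProfile,
    class_abundance,
    de_summary,
    positional_profile,
    report_matrices,
    write_class_abundance_tsv,
    write_profile_tsv,
)
from .reference import (
    ReferenceSequence,
    annotation_name,
    build_ncrna_reference,
    read_reference_fasta,
)

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_files", "read_genome_fasta"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    condition: dict[str, str]
    trim_reports: dict[str, TrimReport] = field(default_factory=dict)
    round1: dict[str, MappingResult] = field(default_factory=dict)
    round2: dict[str, MappingResult] = field(default_factory=dict)
    sample_contigs: dict[str, list[Contig]] = field(default_factory=dict)
    consensus: dict[str, list[ConsensusContig]] = field(default_factory=dict)
    unified_consensus: list[ConsensusContig] = field(default_factory=list)
    clusters: list[Cluster] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)
    annotated: list[AnnotatedFeature] = field(default_factory=list)
    count_matrix: CountMatrix | None = None
    sample_size_factors: dict[str, float] = field(default_factory=dict)
    de_results: dict[str, list[DEResult]] = field(default_factory=dict)
    de_overlap: set[str] = field(default_factory=set)
    profiles: list[FeatureProfile] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def significant_features(self, contrast: str | None = None) -> set[str]:
        names = [contrast] if contrast else sorted(self.de_results)
        out: set[str] = set()
        for name in names:
            out |= {r.feature_id for r in self.de_results[name] if r.significant}
        return out


def _atomic_write_json(data: dict, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(data, indent=2, default=str) + "\n")
    os.replace(tmp, path)


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def run_pipeline(
    reads_by_sample: dict[str, list[ReadRecord]],
    condition: dict[str, str],
    ncrna_sequences: list[ReferenceSequence],
    genome: dict[str, str],
    annotations: list[AnnotationRecord] | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    control_level: str = "control",
    imported_alignments: dict[str, MappingResult] | None = None,
) -> PipelineResult:
    """Run every stage in memory; optionally write the run directory.

    ``condition`` maps each sample to its level; every non-control level is
    contrasted against ``control_level``.  When ``imported_alignments`` is
    given (external aligner output per sample), preprocessing and the built-in
    aligner are skipped and records are routed to round 1 or 2 by whether
    their reference name is a custom-reference id.
    """
    cfg = config or PipelineConfig()
    samples = sorted(reads_by_sample) if reads_by_sample else sorted(imported_alignments or {})
    if not samples:
        raise ValueError("no samples supplied")
    missing = [s for s in samples if s not in condition]
    if missing:
        raise ValueError(f"samples missing a condition label: {missing}")
    levels = sorted(set(condition[s] for s in samples))
    if len(levels) < 2:
        raise ValueError("two conditions required, got " + (levels[0] if levels else "none"))
    if control_level not in levels:
        raise ValueError(f"control level {control_level!r} absent from sample sheet")
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=cfg, condition=dict(condition))
    manifest = result.manifest
    manifest["tool"] = {"name": "srnascan", "version": __version__}
    manifest["parameters"] = cfg.to_dict()
    manifest["rng_seed"] = cfg.rng_seed
    manifest["samples"] = {s: condition[s] for s in samples}
    manifest["stages"] = {}

    def checkpoint(stage: str, info: dict) -> None:
        manifest["stages"][stage] = info
        if out is not None:
            _atomic_write_json(manifest, out / "manifest.json")

    ncrna_ref = build_ncrna_reference(ncrna_sequences, cfg)
    ref_by_id = {r.id: r for r in ncrna_ref}
    checkpoint("build_reference", {"sequences_in": len(ncrna_sequences),
                                   "sequences_out": len(ncrna_ref)})

    preprocessed: dict[str, list[ReadRecord]] = {}
    if imported_alignments is None:
        for sample in samples:
            kept, report = preprocess_reads(reads_by_sample[sample], cfg, sample)
            preprocessed[sample] = kept
            result.trim_reports[sample] = report
        checkpoint(
            "preprocess",
            {s: {"reads_in": r.reads_in, "reads_out": r.reads_out,
                 "reads_trimmed": r.reads_trimmed}
             for s, r in result.trim_reports.items()},
        )
        for sample in samples:
            result.round1[sample] = map_round1(preprocessed[sample], ncrna_ref, cfg)
        checkpoint(
            "map_round1",
            {s: {"alignments": len(m.alignments), "unmapped": len(m.unmapped_read_ids)}
             for s, m in result.round1.items()},
        )
        for sample in samples:
            by_id = {r.read_id: r for r in preprocessed[sample]}
            leftovers = [by_id[rid] for rid in sorted(result.round1[sample].unmapped_read_ids)]
            result.round2[sample] = map_round2(leftovers, genome, cfg)
        checkpoint(
            "map_round2",
            {s: {"alignments": len(m.alignments), "unmapped": len(m.unmapped_read_ids)}
             for s, m in result.round2.items()},
        )
    else:
        ncrna_ids = set(ref_by_id)
        for sample in samples:
            imported = imported_alignments[sample]
            r1, r2 = MappingResult(), MappingResult()
            r2.unmapped_read_ids = set(imported.unmapped_read_ids)
            for aln in imported.alignments:
                if aln.ref_id in ncrna_ids:
                    r1.alignments.append(dataclasses.replace(aln, round=1))
                else:
                    r2.alignments.append(dataclasses.replace(aln, round=2))
            result.round1[sample], result.round2[sample] = r1, r2
        checkpoint(
            "import_alignments",
            {s: {"round1": len(result.round1[s].alignments),
                 "round2": len(result.round2[s].alignments)}
             for s in samples},
        )

    per_sample_intervals = {
        s: alignments_to_intervals(result.round2[s].alignments) for s in samples
    }
    for sample in samples:
        result.sample_contigs[sample] = merge_contigs(per_sample_intervals[sample], sample, cfg)
    checkpoint("contigs", {s: len(c) for s, c in result.sample_contigs.items()})

    for level in levels:
        level_samples = [s for s in samples if condition[s] == level]
        result.consensus[level] = condition_consensus(
            {s: result.sample_contigs[s] for s in level_samples},
            level,
            {s: per_sample_intervals[s] for s in level_samples},
        )
    result.unified_consensus = unify_consensus([result.consensus[lv] for lv in levels])
    checkpoint(
        "consensus",
        {**{lv: len(result.consensus[lv]) for lv in levels},
         "unified": len(result.unified_consensus)},
    )

    read_map = {}
    for contig in result.unified_consensus:
        reads = set()
        for sample in samples:
            for iv, rid in per_sample_intervals[sample]:
                if iv.overlap(contig.interval) >= 1:
                    reads.add(rid)
        read_map[contig.key()] = reads
    result.clusters = cluster_contigs(
        result.unified_consensus, read_map, cfg, cfg.rng_seed
    )
    checkpoint("clustering", {"consensus_in": len(result.unified_consensus),
                              "clusters": len(result.clusters)})

    hit_ref_ids = sorted(
        {a.ref_id for s in samples for a in result.round1[s].alignments}
    )
    known = [
        KnownFeature(rid, annotation_name(rid), ref_by_id[rid].biotype)
        for rid in hit_ref_ids
        if rid in ref_by_id
    ]
    result.features = assemble_feature_set(known, result.clusters)
    novel_features = [f for f in result.features if f.kind == "novel"]
    annotated: list[AnnotatedFeature] = []
    for feat in result.features:
        if feat.kind == "known":
            annotated.append(classify_round1_feature(feat.ref_ids[0], ref_by_id))
    if novel_features:
        tracks = {"main": annotations or []}
        annotated.extend(annotate_features(novel_features, tracks, ["main"]))
    by_id = {af.feature_id: af for af in annotated}
    result.annotated = [by_id[f.feature_id] for f in result.features if f.feature_id in by_id]
    checkpoint("features", {"known": len(known), "novel": len(novel_features),
                            "total": len(result.features)})

    per_sample_alignments = {
        s: result.round1[s].alignments + result.round2[s].alignments for s in samples
    }
    result.count_matrix = count_features(result.features, per_sample_alignments, condition)
    factors = size_factors(result.count_matrix, allow_pseudo_reference=True)
    result.sample_size_factors = dict(zip(result.count_matrix.samples, factors.tolist()))
    checkpoint("counting", {"features": len(result.features),
                            "total_counts": int(result.count_matrix.counts.sum())})

    for level in levels:
        if level == control_level:
            continue
        result.de_results[f"{level}_vs_{control_level}"] = nb_wald_test(
            result.count_matrix, (level, control_level), cfg
        )
    summary, overlap = de_summary(result.de_results)
    result.de_overlap = overlap
    checkpoint(
        "differential_abundance",
        {name: int(sum(r.significant for r in res)) for name, res in result.de_results.items()},
    )

    profiled_classes = {"tRNA", "mt_tRNA"}
    class_of = {af.feature_id: af.assigned_class for af in result.annotated}
    for feat in result.features:
        if feat.kind != "known" or class_of.get(feat.feature_id) not in profiled_classes:
            continue
        feature_length = len(ref_by_id[feat.ref_ids[0]])
        alignments_by_sample = {
            s: [a for a in result.round1[s].alignments if a.ref_id in feat.ref_ids]
            for s in samples
        }
        result.profiles.append(
            positional_profile(
                feat.feature_id, alignments_by_sample, feature_length,
                condition, result.sample_size_factors,
            )
        )
    total_alignments = sum(len(v) for v in per_sample_alignments.values())
    abundance = class_abundance(result.annotated, result.count_matrix, total_alignments)
    checkpoint("profiles", {"profiled_features": len(result.profiles),
                            "classes": sorted(abundance.read_fractions)})

    if out is not None:
        _write_outputs(result, summary, abundance, factors, out)
        checkpoint("report", {"outdir": str(out)})
    return result


def _write_outputs(result: PipelineResult, summary, abundance, factors, out: Path) -> None:
    samples = sorted(result.condition)
    with open(out / "trim_report.tsv", "w") as handle:
        handle.write("sample\treads_in\treads_trimmed\treads_dropped_short\t"
                     "reads_dropped_quality\treads_out\n")
        for s in samples:
            r = result.trim_reports.get(s)
            if r is None:
                continue
            handle.write(f"{s}\t{r.reads_in}\t{r.reads_trimmed}\t{r.reads_dropped_short}\t"
                         f"{r.reads_dropped_quality}\t{r.reads_out}\n")
    contig_dir = out / "contigs"
    contig_dir.mkdir(exist_ok=True)
    for s in samples:
        write_contigs_bed(result.sample_contigs.get(s, []), contig_dir / f"{s}.contigs.bed")
    for level, contigs in result.consensus.items():
        write_consensus_tsv(contigs, out / f"consensus.{level}.tsv")
    write_clusters_tsv(result.clusters, out / "clusters.tsv")
    write_annotated_tsv(result.annotated, out / "features.tsv")
    if result.count_matrix is not None:
        write_counts_tsv(result.count_matrix, out / "counts.tsv")
    for name, results in result.de_results.items():
        write_de_tsv(results, out / f"de.{name}.tsv")
    summary.to_csv(out / "de_summary.tsv", sep="\t", index=False)
    (out / "de_overlap.txt").write_text(
        "".join(f"{fid}\n" for fid in sorted(result.de_overlap))
    )
    write_class_abundance_tsv(abundance, out / "class_abundance.tsv")
    write_profile_tsv(result.profiles, out / "profiles.tsv")
    if result.count_matrix is not None:
        try:
            heatmap, pca, evr = report_matrices(
                result.count_matrix, factors, sorted(result.significant_features())
            )
        except ValueError:
            pass
        else:
            heatmap.to_csv(out / "heatmap_matrix.tsv", sep="\t", float_format="%.6g")
            pca.to_csv(out / "pca_coordinates.tsv", sep="\t", float_format="%.6g")
            with open(out / "pca_explained_variance.tsv", "w") as handle:
                handle.write("component\texplained_variance_fraction\n")
                for i, v in enumerate(evr, 1):
                    handle.write(f"PC{i}\t{v:.6g}\n")


def run_pipeline_files(
    sample_sheet: str | Path,
    ncrna_fasta: str | Path,
    genome_fasta: str | Path,
    outdir: str | Path,
    config_path: str | Path | None = None,
    ncrna_metadata: str | Path | None = None,
    annotation_path: str | Path | None = None,
    control_level: str = "control",
    import_sam: bool = False,
) -> PipelineResult:
    """File-based entry point (the ``run-all`` CLI command).

    The sample sheet is a TSV with columns sample_id, condition, path; the
    path column holds FASTQ files, or SAM/BAM files when ``import_sam`` is
    set.  All inputs are checked before any stage runs.
    """
    sheet_path = Path(sample_sheet)
    rows: list[tuple[str, str, Path]] = []
    with open(sheet_path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("sample_id", "condition", "path"):
            if name not in idx:
                raise ValueError(f"sample sheet missing column {name!r}")
        for line in handle:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(
                (parts[idx["sample_id"]], parts[idx["condition"]], Path(parts[idx["path"]]))
            )
    required = [Path(ncrna_fasta), Path(genome_fasta)] + [p for _s, _c, p in rows]
    if annotation_path is not None:
        required.append(Path(annotation_path))
    if config_path is not None:
        required.append(Path(config_path))
    missing = [str(p) for p in required if not p.exists()]
    if missing:
        raise FileNotFoundError("missing input files: " + ", ".join(missing))

    cfg = load_config(config_path)
    ncrna = read_reference_fasta(ncrna_fasta, ncrna_metadata)
    genome = read_genome_fasta(genome_fasta)
    annotations: list[AnnotationRecord] | None = None
    if annotation_path is not None:
        path = str(annotation_path)
        if path.endswith((".gtf", ".gff", ".gff3")):
            annotations = read_annotation_gtf(path)
        else:
            annotations = read_annotation_bed(path)
    condition = {s: c for s, c, _p in rows}
    if import_sam:
        imported = {s: import_alignments(p) for s, _c, p in rows}
        return run_pipeline(
            {}, condition, ncrna, genome, annotations, cfg, outdir,
            control_level, imported_alignments=imported,
        )
    reads = {s: read_fastq(p) for s, _c, p in rows}
    return run_pipeline(reads, condition, ncrna, genome, annotations, cfg, outdir, control_level)
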