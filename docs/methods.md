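# Methods

This note documents the models and procedures implemented in `srnascan`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Scope and data model

The pipeline takes single-end small-RNA reads (FASTQ) from a two-condition
design (a control level and one or more case levels), a custom small-ncRNA
reference (FASTA plus a TSV sidecar with `id`, `biotype`, `source_set`), a
genome FASTA, and an annotation track (BED6 with an optional biotype column,
or GTF/GFF). Coordinates are 0-based half-open internally and converted at
I/O boundaries. All randomness flows through `numpy.random.default_rng`
seeded from one configuration value, so identical inputs and seeds reproduce
identical outputs byte for byte.

## Preprocessing

Only 3′ adapters are handled (small-RNA read-through leaves adapter at the
3′ end). The longest read suffix matching a prefix of the adapter with at
most `adapter_max_err_rate` (default 0.1) mismatches per matched base, and
at least `adapter_min_overlap` (default 3) bases, is removed. Reads shorter
than `min_read_len` (default 16 nt) are discarded: below that length a
placement against either reference is not trustworthy. When base qualities
are present, reads with mean Phred quality below `min_mean_quality`
(default 17) are discarded; the quality floor is a documented convention —
the filtering criterion is inherently tool-specific — and is configurable.

## Two-round alignment

Round 1 aligns against the dedicated ncRNA reference built by
`build_ncrna_reference`: input sequences longer than `max_ncrna_len`
(default 400 nt) are excluded — the cap is read as "at most 400 nt", since
the focus is small ncRNAs — exact duplicates collapse, and conflicting
sequences under one id are an error. Round-1 placements allow 3′
soft-clipping provided at least `round1_min_match` (16) bases align and
mismatches/matched-length stays **strictly below** `round1_mismatch_ratio`
(0.05). Round 2 takes exactly round 1's unmapped reads to the genome
**end-to-end** (no clipping): mismatches/read-length < 0.023, read length
≥ 18. The two denominators differ deliberately (matched length in round 1,
full read length in round 2), mirroring the two distinct mismatch-ratio
conventions the rounds are specified with.

Scoring is lexicographic — fewest mismatches, then longest matched length —
and *all* co-optimal placements are reported, each record tagged with the
total placement count (`n_hits`, the NH convention). Reads with more than
`max_hits` (100) placements in round 1 are routed onward to round 2; in
round 2 they are discarded and logged.

The built-in engine indexes the concatenated reference with exact k-mers
(`seed_length`, default 10) at every query position and verifies candidates
by ungapped comparison. Seed length 10 is safe by a pigeonhole argument:
with m mismatches in a matched region of length L the longest exact run is
at least ⌈(L−m)/(m+1)⌉, which under the round-1 budget (m < 0.05·L, worst
case L = 21..23 with m = 1) is ≥ 10, and larger under the stricter round-2
budget. Identical read sequences are aligned once and the result broadcast.
Indels are not modelled: the targets are 16–200 nt ncRNAs, splicing is
disabled by design, and substitutions dominate the intended error regime.
The engine is meant for references up to the tens of megabases; for full
genomes use an external aligner and `import_alignments` (SAM/BAM, NH tags
honoured, falling back to per-read record tallies).

## Contigs and consensus

Each alignment record — including every placement of a multimapper —
becomes one strand-specific interval. Per sample, intervals merge
single-linkage when they overlap by at least `contig_overlap` (1) base;
bookended intervals do **not** merge (the merge distance is effectively
−1). Merged intervals supported by fewer than `min_contig_reads` reads are
dropped. The default threshold is ≥ 5 ("a minimum of five reads"); the
stricter > 5 reading is available by setting `min_contig_reads: 6`.

Per condition, the covered base sets of all samples are intersected; each
maximal run of jointly covered bases is a consensus contig — the longest
interval present in every sample of the condition. Supporting counts are
recomputed per sample as the number of alignments overlapping the consensus
interval by ≥ 1 nt (recomputation over the final interval is well-defined,
whereas inheriting member-contig counts is not). The union of the
conditions' consensus sets, with identical intervals deduplicated, feeds
clustering; whether to unify before clustering was an open choice, and the
union preserves loci seen consistently in either condition.

## Representative-contig clustering

Repeatedly: pick the unclustered contig with the highest read count as the
representative (ties: longest, then one seeded uniform draw); every other
unclustered contig sharing at least one read with it is absorbed iff
|reads(c) ∩ reads(RC)| / |reads(c)| ≥ `share_frac` (0.95); emit and remove.
The sharing fraction is **directional** over the candidate member's reads:
that is the only reading under which a high-count locus absorbs its
low-count multimap shadows, which is the operation's purpose. A symmetric
Jaccard variant is available (`jaccard_sharing: true`). Read *identity*
enters sharing fractions; read *multiplicity* (one per placement) enters
read counts.

## Feature set, annotation, counting

Known features are the reference sequences hit in round 1, deduplicated by
annotation name (the id up to a `|source` suffix), so the same gene drawn
from two source sets is quantified once with counts summed over its
entries. Novel features are the representative loci of the clusters.

Novel loci are annotated per source in priority order (specialized small-RNA
sets before general annotation before repeats, when several tracks are
given): within the first source that overlaps on the same strand, the
record with the largest reciprocal overlap
min(ov/len(feature), ov/len(annotation)) wins, ties broken by name. A locus
overlapped only on the opposite strand is classed `antisense`; no overlap
at all leaves it `novel` — the pipeline's endpoint for candidate new
ncRNAs (structure-based classification of such candidates is out of
scope). Biotypes map onto a closed class vocabulary; unrecognized biotypes
fall into the generic lincRNA bucket.

Counting is per alignment: a cell is the number of a sample's alignments
overlapping the feature (same strand, ≥ 1 nt; reference-id match for known
features), so a k-fold multimapper contributes to each locus it overlaps.

## Differential abundance

An explicitly simplified DESeq2-like stage — the contract is statistical
behaviour (FDR control, effect recovery), not bit-compatibility:

- **Size factors**: median over features positive in all samples of
  count/geometric-mean ratios. Factors are defined relative to the
  geometric-mean pseudo-reference (scaling one library scales its factor
  relative to the others). If no feature is positive everywhere, a
  positive-count pseudo-reference fallback is available and the pipeline
  uses it.
- **Dispersion**: method of moments on normalized counts,
  α = (pooled within-group variance − μ·mean(1/s)) / μ², floored at 1e−8;
  a parametric trend α₀ + α₁/μ is fitted by non-negative least squares and
  the final dispersion is max(gene-wise, trended) — a conservative
  shrinkage surrogate (no Cox–Reid adjustment, no MAP fold-change
  shrinkage, no independent filtering).
- **Test**: log2FC = log2((μ_case + 0.5)/(μ_control + 0.5)) from normalized
  group means with a 0.5 pseudo-count guard; SE by the delta method with
  Var(q) = μ/s + αμ²; two-sided normal p on the Wald ratio;
  Benjamini–Hochberg step-up adjustment. Features with all-zero counts are
  excluded (padj = none). Significance is the strict inequality
  padj < `padj_threshold` (0.1).
- **Contrasts** are pairwise, each case level against the control level.

The conservative dispersion choice makes the test under-reject at the
margin; the null simulation in the test suite verifies the achieved
false-discovery fraction stays at or below the nominal 0.1.

## Profiles and reports

Per profiled feature (tRNA and mt-tRNA classes by default) the read-length
histogram is reported per condition as "normalized mean reads": per-sample
counts divided by the sample's size factor, averaged within condition — the
normalization definition adopted for these plots. Offsets are measured from
the feature's 5′ end in feature orientation. The fragment call uses
marginal start- and end-offset histograms: `five_prime_fragment` if ≥ 80%
of reads start within the first 3 nt and the modal length lies in
[25, L−10]; `three_prime_fragment` symmetric from the 3′ end;
`full_length` if the modal length ≥ L−5; `internal` if ≥ 80% of reads both
start beyond the window and end before the terminus; else `mixed`. The 80%
concentration, 3-nt window and modal-length bands are conventions chosen to
make the qualitative biology — 5′ tRNA halves of 32–36 nt versus
full-length 60–68 nt mt-tRNAs — a computable label; all are configurable
(`FragmentRule`). Evaluating on marginals rather than joint (start, end)
pairs is a deliberate simplification.

Class abundance reports per-class read fractions against the total mapped
alignments (leaving room for an unannotated remainder) and unique-feature
counts. Report matrices are log2(normalized count + 1): row-centered rows
for the significant features (heatmap input) and sample PCA coordinates
with explained-variance fractions on the full transformed matrix. No
figures are rendered; outputs are plot-ready tables.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes.
Counts are NB with Var = μ + αμ², matching the test's parameterization.
Feature sequences are uniform random DNA embedded at `copies` loci in a
random scaffold (identical copies ⇒ true multimapping), with annotation
intervals mirroring the placements. Reads are full-length molecules or 5′
fragments (length uniform 32–36 nt, offset 0; an internal 13–20 nt short-tRF
mode exists for classifier tests), with per-base substitution errors
(default 0.002) and constant Q30 qualities. Not modelled: homopolymer
indels, quality decay, ligation bias, adapter contamination beyond an
optional fixed appended adapter. Passing tests therefore demonstrate
correctness of the pipeline's logic and statistics under its own model
assumptions, not robustness to every sequencer artefact.

Three preset cohorts define the study conditions:

- `default_cohort` — the showcase: 10 control vs 15 case samples, 150
  features (miRNA-dominated mix with tRNAs shedding 5′ halves, full-length
  mt-tRNAs, snoRNAs/snRNAs, novel lincRNA/antisense loci, three duplicated
  loci), control means spread log-uniformly over ~15–400, dispersion 0.1,
  a subset of ±4-fold effects, and one miRNA analogue at control mean 2000
  decreased 200-fold in cases.
- `recovery_cohort` — the same 10v15 design and focal 200-fold feature with
  ~40 companion features; used where many replicate end-to-end runs are
  needed, so each run stays in seconds.
- `multimap_cohort` — a minimal 3v3, five-feature design with one
  duplicated locus; used for repeated multimap-collapse checks.

## Numerical and degenerate-input choices

Strict inequalities follow the stated bounds everywhere (mismatch ratios,
padj threshold); the contig read threshold is ≥. Annotation and clustering
ties break deterministically (lexicographic name; seeded draw). Empty
inputs return empty outputs except where a contract requires an error
(empty reference, empty condition, single-condition designs, fewer than two
samples per compared group, fewer than two non-constant features for PCA).
`N` bases never match anything. BH adjustment validates p ∈ [0, 1].

## Known limitations

Ungapped desk-scale aligner (import external alignments for full genomes);
single-factor two-level contrasts only (no covariates, no outlier
replacement); no structure-based annotation of novel candidates; fragment
calls from marginal histograms; simulation error model is
substitution-only.
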