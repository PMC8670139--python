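# Methods

## Scope and data model

`uprseq` operates strictly downstream of read alignment and quantification:
its inputs are gene × sample FPKM tables with a sample design
(strain ∈ {WT, hac1}, treatment ∈ {none, DTT, TM}, timepoint ∈ {0, 15, 30,
60} min, replicate 1–3).  The 0-min sample is the shared untreated control
for both drug series and must carry treatment `none`.  Values must be
non-negative and complete — missing cells are load-time errors, never
imputed, because nothing downstream defines behaviour for imputed
abundances.  Replicate-level FPKM is required (not replicate-averaged):
the strain-comparison t-test needs per-replicate observations.

## Relative abundance and trajectories

Relative transcript abundance at time *t* is
`(mean FPKM at t + ε) / (mean FPKM at 0 min + ε)` with pseudocount
ε = 0.01 FPKM on both numerator and denominator.  The pseudocount only
matters for essentially silent genes; for genes with FPKM ≥ 1 it moves
ratios by < 0.1%.  Per-replicate log2 relative abundances divide each
treated replicate by the **mean** of the untreated replicates — replicates
are unpaired biological cultures, so there is no meaningful pairing.

A gene's trajectory under one drug is the vector of adjacent-timepoint
differences of log2 relative abundance,
x = (log2rel(15) − 0, log2rel(30) − log2rel(15), log2rel(60) − log2rel(30)),
with the implicit 0 at t = 0; the three components telescope to
log2rel(60) exactly.

## Differential expression

The default internal engine is deliberately plain: per-gene two-sided Welch
t on log2(FPKM + ε), treated vs 0-min replicates, Benjamini–Hochberg
adjusted across all genes.  UP requires linear fold change > 2 and
q < 0.1; DOWN requires fold change < 0.5 and q < 0.1.  Two thresholds
circulate for this kind of design (0.05 and 0.1); the default is 0.1 and
both are exposed in the config rather than resolved silently.  Because no
simple engine reproduces any particular upstream DE caller, externally
computed q-values can be supplied (`q_source: provided`) and the rule layer
then reproduces any upstream caller's partition exactly.  Venn-region
counts over the UP/DOWN sets are exact set cardinalities.

## Induction-group classification (the χ² trajectory statistic)

Four induction archetypes are anchored by curated reference genes (A:
rapid DTT, DER1/HRD1/UBC7; B: gradual DTT, KAR2/LHS1/ERO1/MPD1/PDI1; C:
gradual TM, KAR2/ERO1/PDI1; D: late TM, SEC12/SEC24/SFB3/HRD3).  Group
fitting computes μ_i (mean) and ν_i (variance) of the reference genes'
x-vectors; a candidate gene is scored by
`χ² = Σ (x_i − μ_i)²/ν_i`, referred to χ²₃ under the assumption
x_i ~ Normal(μ_i, ν_i) independently.  Large upper-tail P selects:
P > 0.1 (A, B) or P > 0.05 (C, D), with an extra linear fold change > 4 at
15-min DTT for group A.  Candidates are genes UP at ≥ 1 timepoint of the
group's drug (`candidate_mode: any`; `all` is available for a stricter
reading).

Numerical and statistical choices:

* ν uses the unbiased n−1 denominator by default (`variance_ddof`); with
  3–5 references the choice is material, hence configurable.
* ν_i ≤ 1e−8 is rejected as a degenerate configuration instead of
  producing unbounded statistics.
* Reference genes are scored against their own full-group μ/ν (no
  leave-one-out), are always reported as members of their group, and carry
  a `reference_<group>` flag so the forced membership is auditable.
* No multiplicity correction is applied to the selection (the rule
  thresholds raw P; large-P selection has no standard correction); a BH
  column is emitted for information only.
* **Fragility of refitted parameters.** With 3 references, ν̂ has 2
  degrees of freedom; under realistic replicate noise (CV 20%, n = 3, which
  adds ≈ 0.056 log2² of measurement variance to each x-component) ν̂ can
  undershoot several-fold, inflating χ² for genuinely group-like genes.
  Classification quality against *refitted* parameters therefore varies
  substantially from experiment to experiment; the planted-recovery
  validation scores against the known generating parameters, which is the
  regime in which the uniform-P calibration (recall ≈ 1 − p-threshold)
  holds.  This is an intrinsic property of anchoring a 3-parameter
  statistic on 3–5 exemplar genes, not an implementation artifact.

## UPR designation (Hac1 dependence)

Each ESRT is tested in every group it belongs to, at the group's peak
timepoint (A: 15-min DTT; B: 60-min DTT; C/D: 60-min TM) — the *hac1*Δ
strain is sampled at 15 and 60 min only, so 30-min requests are
configuration errors.  The test compares per-replicate log2 relative
abundances (each strain normalized to its own untreated control), two-
tailed, p < 0.05; a gene significant in ≥ 1 of its groups is a UPR target.

The default is the **pooled** two-sample t.  At n = 3 vs 3 the pooled test
is exactly calibrated under equal variances (measured type I 0.050 at
α = 0.05), whereas Welch–Satterthwaite under-rejects (0.035) because the
estimated df collapses toward 2; with equal group sizes the two tests share
the same t statistic and differ only in df, so the choice affects
calibration, not ranking.  `equal_var: false` selects Welch for users who
prefer robustness to variance heterogeneity over exact small-n calibration.

A curated override list (default: UBC7, an ERAD E2 whose Hac1-dependent
induction is established experimentally) can force designation; overrides
must name ESRTs, must carry a rationale note, and never alter the
statistical fields.

Caveat worth knowing: because each strain's replicates share one estimated
0-min baseline, the strain comparison carries a per-strain baseline shift
(SD ≈ 0.17 log2 at CV 20%, n = 3) that between-replicate variance cannot
see.  Run end-to-end through noisy baselines, the effective false-positive
rate of the designation is ≈ 0.10–0.12 rather than the nominal 0.05.  The
designation's operating characteristics are therefore validated at the
observation level (i.i.d. replicate noise around each strain's true level),
which isolates the test itself; the end-to-end rate is a property of the
experimental design (one baseline per strain), and any analysis of such a
design inherits it.

## UPRE motif scanning

UPRE-1 (`CASNGKD`) and UPRE-2 (`ACGTGKY`) are 7-bp IUPAC consensuses.  The
scanner tests every offset (overlapping hits all reported) on the coding
strand and, by default, the reverse complement as well — bZIP binding is
orientation-tolerant; `strands: coding` reproduces a stricter single-strand
reading.  Coordinates are 0-based half-open internally; reported positions
are start-codon-relative with −1 the base immediately 5′ of the ATG, and a
hit's position is the coding-strand coordinate of its leftmost base.
Ambiguous bases in promoters never match.  Promoters default to 1000 bp
upstream of the start codon (extracted from genome FASTA + GFF3, clipped
and flagged at contig edges; minus-strand genes are reverse-complemented).

Expect chance matches: UPRE-1 matches 48 of the 16384 7-mers
(≈ 2.9 hits/kb/strand on uniform background), UPRE-2 matches 4.  With a
1-kb double-stranded window nearly every promoter contains a chance UPRE-1
word, so the per-gene labels (UPRE1_only/UPRE2_only/both/none) are most
informative with shorter windows or downstream conservation filtering; raw
counts are emitted so stricter readings (e.g. exactly-one) can be applied.

## Genetic-interaction scores

Trait values come in two conventions: `relative` (T = mean(mutant)/mean(WT),
the literal reading) and `deviation` (T = relative − 1, the default).  The
interaction is I = T_AB − (T_A + T_B) — grouped that way so the value is
bitwise symmetric in the two genes.  Only the deviation convention makes
"I near zero = additive" coherent for modest effects: two no-effect single
deletions with a no-effect double give I = 0 under deviation but I = −1
under raw relative.  Labels use a tolerance τ (default 0.1, a qualitative
cutoff: the underlying wet-lab comparisons report significance stars, not a
numeric threshold).  An optional percentile bootstrap (replicate resampling,
seeded) provides an interval on I; with n = 3 replicates it is indicative
rather than exactly calibrated.

## Synthetic-data generator

The generator emulates the study design downstream of quantification:
replicate FPKM = baseline × 2^(planted log2 trajectory) × log-normal noise.

* **Baseline**: ln FPKM ~ Normal(3.9, 1.5²) — a broad, realistic bulk
  expression distribution.
* **Replicate noise**: multiplicative log-normal, unit mean, CV 20% —
  typical biological-replicate scatter for bulk RNA-seq of cultures.
* **Archetypes** (log2 relative abundance at 15/30/60): groupA (3.0, 1.8,
  1.2) DTT — rapid induction peaking at 15 min then decaying; groupB (0.8,
  1.8, 2.8) DTT and groupC (0.8, 1.6, 2.4) TM — gradual induction; groupD
  (0.0, 0.2, 1.8) TM — flat until 30 min, induced late; plus flat, down and
  noisy_up backgrounds.  Magnitudes were set so that a planted group gene
  clears the DE gate (fold change > 2) and group A's 15-min fold change > 4
  gate with several standard deviations of margin under default noise —
  a planted "induced" gene that fails its own induction gate would
  contradict its truth label.  For the same reason, member draws are
  rejection-sampled against per-archetype induction floors (groupA:
  x₁ ≥ 2.6; B/C/D: 60-min level ≥ 1.6); the floors trim only the far left
  tail, leaving the χ² calibration essentially intact.
* **Reference planting**: reference genes are planted *deterministically*
  with sample mean exactly μ and sample variance exactly ν (centered,
  variance-standardized offsets), so group fitting recovers the configured
  parameters up to replicate noise.  Ordinary members draw
  x_i ~ Normal(μ_i, ν_i) — precisely the model the χ² statistic assumes.
* **Reference spread** ν = 0.5 log2² per component (SD ≈ 0.7 log2, i.e.
  co-regulated references differing ~1.6-fold per interval, 1σ).  The
  spread must dominate the replicate-noise contribution to a measured
  x-component (≈ 0.056 log2²) for trajectory distances to be meaningful;
  at ν = 0.25 the noise inflation alone caps asymptotic group-A/B recall
  below 0.85, so 0.25 was excluded analytically and 0.5 chosen as the more
  conservative of the values that clear the bar.
* **Hac1 dependence**: 85% of group-like genes are Hac1-dependent (most
  stress-induced genes in this system are UPR targets); their induction is
  divided by the attenuation factor (default 4, i.e. −2 log2) in the
  *hac1*Δ matrix.  All planted references are dependent except UBC7,
  deliberately planted independent so the curated-override path is
  exercised end-to-end.
* **Promoters**: i.i.d. bases at configurable frequencies (uniform
  default); planted motifs are concrete 7-mers drawn uniformly from the
  consensus match set, written at non-overlapping uniform positions on a
  uniform random strand and recorded in the truth table.  Background
  matches arise on top and are not in the truth.
* **Activities**: WT mean 1; single-mutant means 1 + T; double means
  1 + T_A + T_B + I; log-normal replicate noise, CV 5% (enzyme assays are
  much tighter than RNA-seq replicates), n = 3.

All three generators are pure functions of (config, seed): identical
inputs give byte-identical outputs.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: gene-length/GC quantification biases, correlated
(batch) replicate noise, count-level mean–variance relationships at low
expression, promoter base composition and motif clustering, and partial
(dose-dependent) Hac1 dependence.  Recovery rates on synthetic data are
upper bounds for real experiments.

## Pipeline and reproducibility

The YAML config is schema-validated (unknown keys rejected); stages run in
dependency order and skip cleanly when their inputs are absent.  Every
output table carries a provenance header (package version, config hash,
seed); numeric output uses 6 significant digits; summary counts are
recomputed from the tables and cross-checked (UPR targets ⊆ ESRTs ⊆
upregulated genes ∪ flagged references).  Runs are deterministic to the
byte; the run log records stages and counts but no wall-clock timestamps.

Validation problem sizes (10,000 draws for oracle/calibration checks,
4 × 50 planted group genes over 500 flat background, 1,000 1-kb promoters,
500 interaction datasets, a 1,000-gene end-to-end bundle) were chosen so
each check's sampling error is several times smaller than the property
margin it verifies while the whole validation completes in seconds.

## Known limitations

* The χ² trajectory selection has no error control in the usual sense —
  large-P selection rewards *lack of evidence of difference*, and its power
  to exclude depends entirely on how well 3–5 references pin down μ and ν.
* The internal DE engine is a convenience, not a replacement for
  count-based DE callers; supply external q-values to reproduce a specific
  caller.
* UPRE labels from a 1-kb double-stranded window are background-dominated
  for UPRE-1 (see above).
* Bootstrap intervals at n = 3 replicates are indicative only.
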