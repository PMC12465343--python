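# Methods

## The model

`semburden` implements a stochastic-epigenetic-mutation (SEM) analysis of
case/control DNA-methylation cohorts, with a downstream multi-omic
prioritization of regulatory features and genes. The running example
throughout the package is a juvenile-idiopathic-arthritis-like design: two
groups of patients (ID, who maintain inactive disease after therapy
withdrawal, and NO_ID, who do not), profiled at two timepoints (T0 =
withdrawal, Tend = eight months later), with beta-value methylation and
log-scale expression per sample.

A SEM at CpG *j* in sample *i* is a beta value outside

    [Q1_j − k·IQR_j,  Q3_j + k·IQR_j],    k = 3,

where the quartiles are computed over a fixed reference cohort — the ID
patients at T0 — and applied to every sample at both timepoints. The
comparison is strict: values exactly on a bound are not outliers. The
epigenetic mutation load is EML_i = ln(total SEM count of sample *i*).
Group differences in EML (or any per-sample biomarker) are tested by OLS of
the biomarker, standardized to unit SD over the analysis sample, on the
activity indicator with age and sex as covariates; the coefficient reads as
a standard-deviation difference, with t-based confidence intervals.

Per-region inference aggregates the binary per-CpG SEM indicators of a
feature (a TF-binding-site CpG set, or a pathway CpG set) into the SKAT-O
family of statistics

    Q_ρ = (y − μ)' Z W R_ρ W Z' (y − μ),   R_ρ = (1−ρ) I + ρ 11',

under a logistic null of activity on age and sex. ρ = 0 is the
variance-component (SKAT) kernel, ρ = 1 the squared weighted burden. Site
weights follow the rare-variant convention, the Beta(1, 25) density
evaluated at the per-site SEM frequency; uniform weights are selectable.
Per-ρ null distributions are mixtures of one-degree chi-squares whose
weights are eigenvalues of the covariate-projected kernel; tail
probabilities come from numerical inversion of the characteristic function
(Imhof's formula, composite Simpson on an oscillation-resolving grid, exact
for a single eigenvalue) with a Liu-type moment-matching fallback. The
SKAT-O p-value corrects the minimum over the ρ grid
{0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1} through the one-dimensional
mixture integral (the ρ = 1 point is capped at 0.999 inside the
combination, as is conventional); the reported p is clamped to
[min_ρ p, min(1, |grid|·min_ρ p)]. A permutation mode (residual
permutation, ensemble-rank per-ρ p-values, min-p combination) provides an
exactly calibrated small-sample alternative.

Feature selection runs three independent routes on the samples × features
burden matrix at Tend: SKAT-O with Benjamini–Hochberg FDR (q < 0.1),
elastic-net logistic regression (selected = non-zero coefficients,
importance = |coefficient|), and gradient-boosted trees (importance =
split count). The classifiers use stratified 5-fold cross-validation with a
grid search scored by average precision, which is robust to the 30:14
imbalance; no resampling or class weighting is applied by default. The
consensus is the three-way intersection, ordered by mean normalized rank
with lexicographic tie-breaks.

Consensus TFs are expanded to hub genes (genes targeted by many consensus
TFs); candidates require targeting by at least 50% of them (inclusive).
Candidates are filtered by per-gene Welch contrasts of expression at Tend
(NO_ID − ID), BH-adjusted within the candidate list only, significant at
q < 0.2 (an option reads the raw p instead — both behaviours appear in the
literature this pipeline emulates). Significant genes become an up/down
signature, ordered by absolute effect, exported as two plain lists plus a
GMT for connectivity-map queries. Exported CMAP result tables are filtered
on FDR q < 0.05, negative normalized connectivity score, and an
immune-relevant cell-line allow-list (JURKAT, THP1, K562, HL60, BJAB,
NALM6, CD34). External-validation effects are pooled per gene with a
DerSimonian–Laird random-effects meta-analysis.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions used throughout the acceptance checks:

| parameter | default | meaning |
| --- | --- | --- |
| n_id / n_noid | 30 / 14 | group sizes (subjects; two samples each) |
| n_cpg | 20,000 | CpGs (desk-scale stand-in for a 450K array) |
| n_tfbs / n_pathway | 40 / 60 | feature sets (scaled from 159 / 358) |
| cpgs_per_feature | 500 | CpGs per feature set |
| base_sem_rate | 1e-3 | per-CpG per-sample outlier probability |
| enrichment_factor | 5 | NO_ID rate multiplier inside enriched features |
| n_enriched_features | 5 | truly enriched TFBS features |
| n_genes / n_de_genes | 2,000 / 40 | genes; truly shifted genes |
| de_effect_size / noise SD | 2.0 / 0.5 | log-expression shift / residual SD |
| ages | ID ~ N(9.91, 3.55), NO_ID ~ N(13.42, 3.69), clipped to [2, 18] | cohort structure |
| sex | P(F) = 0.70 both groups | cohort structure |

Per-CpG baselines are Beta draws around a bimodal mean profile (45%
low-methylated, 45% high, 10% intermediate; concentration 30–120), giving
the familiar two-hump marginal of array methylomes. Injected SEMs replace
the baseline value with a uniform draw strictly outside 3×IQR bounds
pre-estimated from the simulated ID-at-T0 baseline, on the side with room;
CpGs whose bounds already cover [0, 1] are not injectable. No empirical SEM
rate is published for this design, so the base rate is an arbitrary but
realistic choice (~20 outliers per sample at 20,000 CpGs, matching the
order of magnitude seen on real arrays after 3×IQR calling); it is a
documented default, not a fitted quantity. TFBS features draw ~30% of their
CpGs from a shared "hub" pool so that hub genes targeted by many TFs exist,
as they do in real ChIP-seq annotations; true DE genes are drawn from genes
downstream of ≥50% of the enriched TFs and shifted by ±de_effect_size in
NO_ID at Tend only.

What the generator does not emulate: probe-type chemistry, batch effects,
within-subject correlation across timepoints, flare dynamics, and
overdispersion of SEM counts beyond what quantile-estimation noise induces.
Passing tests therefore demonstrate the pipeline's statistical machinery
and its power under clean Poisson-like burdens, not robustness to array
artifacts.

## Numerical and design choices

- **Quantile convention.** Linear interpolation between order statistics
  (the default of mainstream statistical environments). SEM counts depend
  on it, so the convention is stored on the bounds object and configurable.
- **Zero-SEM samples.** EML defaults to ln(count + 1) = 0 for zero counts
  with a warning (counts ≥ 1 keep ln(count)); a strict policy reports them
  missing instead.
- **In-sample reference bias.** Reference (ID-at-T0) samples sit inside
  their own empirical quantile bounds more often than out-of-reference
  samples, so T0 contrasts against the reference group are inflated — a
  genuine property of reference-cohort outlier calling, visible in the
  generator's null runs. Truth-recovery checks therefore read the Tend
  contrast, where both groups are out-of-reference.
- **Analytic vs permutation SKAT-O.** The chi-square-mixture null assumes
  approximately Gaussian score residuals. With 44 samples and sparse binary
  sites that approximation degrades (a literature-known small-sample
  issue), so the permutation mode is the recommended and tested path at the
  study size; the analytic path is verified against Monte-Carlo mixture
  tails directly, and against a 10^4-permutation oracle on a dense-event
  cohort (thousands of samples, 5% site rate, intercept-only null so the
  oracle is exactly exchangeable) — the regime where its Gaussian-score
  assumption holds. The approximation error decays with the number of
  events per site, not with sample size alone.
- **Standardization.** Feature scaling uses the population-SD convention
  (divide by n), matching the common ML-preprocessing default; the
  association op standardizes with ddof = 1 over the analysis sample.
- **Filter order.** Detection-p mask → CpG (row) call-rate filter → sample
  (column) call-rate filter → median imputation; the row/column order is
  configurable because the underlying workflow description does not fix it.
  All call-rate and missingness comparisons are strict, boundary cases
  retained.
- **Hyperparameter grids.** Shipped defaults are small, desk-scale grids
  (elastic net: C ∈ {0.01, 0.1, 1}, l1_ratio ∈ {0.2, 0.5, 0.8}; XGBoost:
  ≤100 trees, depth ≤ 3), stand-ins for supplementary-grade tuning.
- **Problem sizes.** Tests and the acceptance script use 20,000-CpG
  cohorts, 100 seeds for effect-recovery, 20 seeds for consensus recovery,
  500 features for null calibration and 10^4 permutations for oracles —
  sizes chosen to make the statistical checks decisive on a single CPU.
- **Determinism.** All randomness flows from a single config seed through
  named substreams (annotation, cohort, methylome, expression); pipelines
  rerun bit-identically per seed.

## Known limitations

- The analytic SKAT-O p at n ≈ 44 with very sparse sites should not be
  trusted at face value; use the permutation mode (this is also why no
  small-sample moment correction is enabled by default — the permutation
  path supersedes it).
- Genomic-coordinate intersection is out of scope: annotations arrive as
  pre-resolved CpG-id GMT sets.
- DE uses Welch contrasts without covariates by default; an age+sex
  adjusted option exists but mirrors the unadjusted published design.
- The CMAP interaction is file-based only: the package writes signature
  files and filters exported result tables; it never queries the service.
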