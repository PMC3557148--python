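# Methods

This note documents the models, estimators and numerical choices behind
`stqc`, and what the synthetic cohorts do and do not establish about
real data.

## Quality metrics and the flag rule

Three per-array metrics are combined:

- **CV** = sample SD / mean over all probes of an array, on the raw
  linear scale. The ceiling is mean + 2·(sample SD) of the CVs of
  high-integrity arrays (RIN > 6); an array fails above it. The
  direction (one-sided upper) follows the observation that degradation
  inflates probe-level dispersion.
- **PM−BG** = mean(perfect-match) − mean(background) on the linear
  scale. No published numeric rule exists for this metric, so the CV
  construction is mirrored: fail below mean − 2·SD of the high-RIN
  arrays.
- **Median GNUSE**. After frozen preprocessing, each cluster's standard
  error is divided by the frozen reference median for that cluster, and
  the array is summarised by its median across clusters. Values are ~1
  for a typical reference-quality array; the flag threshold is 1.25
  (precision ~25% worse than the reference population).

An array failing at least two of the three is flagged. Arrays are
ranked worst-first by median GNUSE, ties broken by array id. SD
conventions: sample SD (n−1) in threshold construction and the cohort
RIN summary; population SD (n) for the flagged-group RIN summary —
these are the conventions under which the packaged cohort's printed
summaries are reproduced. The purity test (A260/230 by flag status)
defaults to the classical equal-variance Student's t, which reproduces
the packaged cohort's p = 0.14 (Welch gives 0.095 and is available via
`equal_var=False`).

## Frozen-reference preprocessing

Frozen parameters are built once from a reference collection of
high-quality arrays (≥ 3, typically 20–30): mean-of-sorted-columns
quantiles; per-probe affinities φ_p = median across reference arrays of
(log2 value − cluster median), centred to sum to zero within each
cluster; and per-cluster reference SE medians. New arrays are processed
one at a time: log2 (with a 0.5 pseudo-floor), quantile map onto the
frozen quantiles (ties receive the mean of the quantile values they
span), then per cluster expression = median of (value − φ_p) and
SE = 1.4826·MAD/√n_probes.

This is deliberately a *dialect* of frozen-parameter preprocessing:
median/MAD replaces robust weighted least squares, and no convolution
background correction is applied (background probes serve only the
PM−BG metric). The construction is deterministic, exactly
reproducible, and sufficient for precision scoring; it does not
numerically reproduce any specific published frozen-vector set.

A measured caveat: when a cohort carries many strong true effects,
forcing every array onto the same frozen quantiles leaks a small amount
of signal into null genes (their fold changes acquire an extra ~0.07
log2 spread in our simulations). Null-cohort calibration is clean (see
below), but adjusted p-values on effect-rich cohorts are mildly
anti-conservative — a property shared by any frozen quantile method.

## Batch/quality adjustment (empirical Bayes) and SVA

`combat_adjust` implements the standard parametric location/scale
empirical-Bayes adjustment: gene-wise standardisation against the
overall fit (protecting the biological design), per-batch location and
scale estimates shrunk toward across-gene moment-matched priors (normal
and inverse-gamma), joint posterior by fixed-point iteration (tolerance
1e-4, max 100 iterations), and back-transformation. A single batch
level is the identity. The quality adjustment is the same routine with
flag categories as "batches", applied after batch adjustment. Disease
status is protected by default. The implementation agrees with the
Bioconductor parametric ComBat to its convergence tolerance (cross-checked
in the test suite via Rscript).

`estimate_num_sv` counts residual singular values whose
variance-explained proportion beats a permutation null (each gene's
residuals permuted independently, residuals re-projected, 100
permutations, significance 0.10, counted from the largest until the
first failure). `estimate_sv` builds each surrogate from the genes
significantly associated with the corresponding residual singular
vector (correlation-test p < 0.05, at least 50 genes), taking the SVD
of that subset and returning the component most correlated with the
original vector; columns are orthonormalised. Because a pair of equally
strong factors is only identified up to rotation of its span, recovery
is assessed by the multiple correlation of each planted factor on the
surrogate span.

## Differential expression

Gene-wise (weighted) least squares with a common design; contrast fixed
to tumour − normal. Patient pairing is not modelled (disease, quality
and batch enter as fixed effects only). Moderated t-statistics shrink
the residual variances toward a scaled-inverse-chi-square prior fitted
by digamma/trigamma moment matching on log s²; an infinite prior df
(no excess spread) collapses to the plain mean of the variances, and
the total df is capped at the pooled residual df — both choices match
limma, against which the chain is cross-checked to 1e-8. BH adjustment
delegates to statsmodels after validation.

Array quality weights assume var(ε_gj) = σ_g²/w_j and alternate
gene-wise WLS with a leverage-corrected moment update of the array
factors, normalised to geometric mean 1 (product 1); non-convergence
after 50 iterations yields the last iterate with a warning.

The five strategies consume batch-corrected expression: `weights`
(estimated array weights in the fit), `exclude` (drop flagged arrays;
≥ 3 arrays per group required), `combat` (quality-category adjustment
then plain fit), `covariate` (quality flag + batch dummies in the
design; an ordinal GNUSE covariate would be a simple extension),
`sva` (surrogate columns in the design). No fold-change cutoff is
applied by default. Hierarchical clustering is average-linkage on
either Euclidean or 1 − Pearson distances (both published descriptions;
the package exposes both and defaults to 1 − Pearson for the
before/after adjustment comparison).

## Degradation bias

`quality_affected` reruns the identical lm → moderated-t → BH chain
with the QC flag as grouping factor; clusters with adjusted p ≤ 0.05
and |FC| ≥ 2 (defaults; the stricter 0.01 used for some published
figures is exposed) are classed up/down by sign. Length bias is tested
by one-sided Mann–Whitney (up-class shorter, down-class longer than
unaffected; exact null for groups ≤ 8, tie-corrected normal
approximation otherwise). Positional profiles average log2 intensity by
5'→3' probe position over clusters with exactly k probes.

## qPCR statistic

FC = e_t^ΔCt_t / (∏ e_i^ΔCt_i)^(1/n_refs), ΔCt = Ct_normal −
Ct_tumour (so FC > 1 means higher in tumour), triplicates averaged
before ΔCt. The geometric-mean reading of the normalising denominator
(exponent 1/n over the reference set) is adopted because the
normalisation is defined as the geometric mean of multiple control
genes; with all efficiencies 2 the statistic reduces exactly to
2^(ΔCt_t − mean ΔCt_refs). Efficiencies are supplied per primer
(dilution-series fitting is out of scope) and must lie in (1, 2].
Array agreement is summarised by OLS of log2(qPCR FC) on the array
log2 FC with adjusted R² = 1 − (1−R²)(n−1)/(n−2).

## The synthetic cohort generator

Log2 PM intensity of probe p (cluster g, position t) on array j:

    y = mu_g + (delta_g + u_g,pat(j))·I[tumour] + b_g·I[batch2]
        + q_j·(gamma_g − c) + eta_gj + phi_p + s·(t−1)/(k−1) + eps_pj

- **Degradation level** q = clip((7 − RIN)/5, 0, 1): zero at the
  conventional "safe" RIN of 7, saturating at RIN 2. RINs are drawn
  from a two-component mixture (high ~ N(7.5, 0.8²) with weight 0.75,
  low ~ N(3.0, 0.5²) with weight 0.25, truncated to [2, 10]).
- **Length bias** gamma_g = −0.4·log2(length_g/L0), L0 the median
  simulated length: long transcripts lose signal on degraded arrays,
  short ones gain. Lengths are log-normal (median 2400 bp, log2 SD
  1.2), with 10% of clusters set to short non-coding lengths (< 400 bp).
- **Global PM attenuation** c = 0.5 log2 units per unit q, so PM−BG
  falls with degradation.
- **Noise** eps has SD σ0·(1 + λq) with σ0 = 0.3 and λ = 2. λ, κ and c
  are free simulator parameters — the quantitative degradation→noise
  relationship is not published — chosen so that degradation dominates
  condition-driven CV differences, which is the regime in which the QC
  metrics are meaningful.
- **Biology.** delta_g is nonzero for 10% of clusters (|log2FC|
  uniform in [1, 2], random sign). Patient-level heterogeneity u (SD
  0.5) applies only to truly differential clusters, so every non-DE
  cluster is exactly null — required for truth-based error-rate
  measurement. Sample-level variability eta (SD 0.25) applies to all
  clusters and, being a property of the RNA sample, is shared with the
  matched qPCR generator. Three non-DE clusters are designated
  housekeeping references with reduced biological SD (0.1), reflecting
  their selection for stability.
- **Structure.** 17 patients ⇒ 34 paired arrays in batches of 10 and
  24 (pairs never split); per-gene additive batch effect (SD 0.3);
  background probes from a fixed low-mean log-normal; optional 3'-bias
  slope s (off by default) to emulate oligo-dT-style positional trends.
  Reference arrays come from the same universe with q = 0 and no
  condition or batch terms. All draws flow from named substreams of a
  single configured seed; every artifact is deterministic.

The qPCR generator writes Ct = A − θ·ln2/ln(e) + N(0, σ_ct²) per
replicate with θ the planted log2 abundance, so the
efficiency-corrected fold change recovers 2^(planted log2 FC) exactly
at σ_ct = 0.

### What the simulations show — and what they do not

The generator reproduces the *structure* the analysis assumes:
RIN-linked precision loss, a signed transcript-length bias, additive
batch effects, and two latent factors (batch, degradation) in the
residuals. Passing tests demonstrate that the estimators recover
planted truth under that structure at realistic sizes. They do not
demonstrate robustness to features the generator omits: probe
GC-content effects, spatial artifacts, FFPE chemistry,
sequence-specific degradation, or annotation error. Effect sizes are
strong enough that all five strategies saturate sensitivity on default
cohorts; the comparison "compensation ≥ exclusion" is therefore
evaluated at matched empirical FDR rather than at a fixed threshold
alone.

### Tie-aware operationalisations

Roughly half the simulated arrays have exactly q = 0 (RIN ≥ 7), so any
rank correlation computed across *all* arrays against q is capped well
below 1 by the tie block, and realized per-array CV is heavy-tailed.
Monotonicity properties are therefore tested on the scale on which they
are stated: mean CV by degradation bin (q = 0 bin plus quintiles of
q > 0, arrays pooled over five cohorts) must be rank-perfect in q; and
array-weight recovery is tested as Spearman > 0.7 against q among
degraded arrays plus the requirement that every flagged array's weight
falls below the median passed weight.

### Null calibration

On null cohorts (no planted effects) raw moderated-t p-values are
uniform (KS ≈ 0.02 at 2000 clusters). The false-discovery rate of BH at
nominal 0.05 is estimated over balanced relabelings of the condition on
null cohorts — each relabeling is a valid null draw by exchangeability,
and every discovery is false — giving ≈ 0.05, within the 0.07 bound
used by the acceptance checks. A single pure-null dataset yields only a
0/1 outcome for FP/max(R, 1), which is why the relabeling estimate is
used.

## Problem sizes

Default simulated cohorts are 2000 transcript clusters × 25 PM probes
(+500 background probes) × 34 arrays with a 30-array reference set —
the scale at which the acceptance checks run. Unit and property tests
use 200–2000 clusters with 4–10 probes per cluster; each size is stated
in the test that uses it. The packaged QC table is the full 34-array
cohort summary with its printed pass/fail calls and ranks (including
the source's own gap at CV fail rank 6, kept verbatim); its batch
column is a synthetic assignment consistent with the 10/24 split and
unsplit pairs, and nothing computed from the table depends on it.

## Known limitations

- The frozen preprocessing is a faithful-in-spirit dialect, not a
  numeric re-derivation of published frozen vectors; GNUSE values are
  comparable within this package only.
- Adjusted p-values on effect-rich cohorts inherit a mild quantile-
  normalisation anti-conservatism (measured above).
- Patient pairing is not modelled in the linear model; a paired design
  would gain power but is out of scope.
- The covariate strategy treats quality as the binary flag; the
  continuous GNUSE score is available in the QC report but not wired
  into the default design.
- Pathway-level evaluation and reference-gene stability ranking are out
  of scope; reference genes are fixed.
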