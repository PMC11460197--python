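# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions that results depend on.

## Synthetic data model

The generator produces a two-set, multi-batch TMT-like plasma experiment
with known ground truth. On the log2 scale, a biological measurement is

    log2 x_ij = b_i + δ_i·1{AD_j} + Σ_c β_ic·c_j + γ_{i,batch(j)} + ε_ij

with

- **b_i** — base abundance, log10-uniform over 10 orders of magnitude
  (`base_abundance_log10 = (0, 10)`), matching the dynamic range of a
  heparin-enriched plasma proteome. Because the scale is log-uniform, the
  per-sample intensity sum is dominated by the few most abundant proteins,
  which is what makes channel-sum scaling informative and also what creates
  mild compositional coupling — both realistic.
- **δ_i** — true AD-vs-control log2 fold-change; a fraction
  `frac_de = 0.10` of proteins draw δ from N(0, 0.5²), the rest are exactly
  zero (the "null block" used for calibration checks).
- **β_ic** — per-protein covariate slopes, N(0, σ_c²) with small defaults
  (age 0.002 log2/yr; sex and race contrasts 0.05 log2): covariate nuisance
  exists but does not dominate.
- **γ_ib** — protein-specific additive batch offsets, N(0, 0.4²). This is
  exactly the structure a median-polish-of-ratios harmonization removes.
- **ε_ij** — residual noise, sd 0.3 log2 (technical + inter-individual).
  Within each latent module the residuals share a per-sample factor so that
  the within-module correlation equals `module_purity` (default 0.9,
  10 modules of 30 proteins — roughly the 44-module consensus brain network
  scaled to a 2000-protein matrix).

Batch assignment is randomized **stratified by diagnosis** (group-by-batch
counts differ by at most one), as in the emulated study design. Each GIS
channel is the arithmetic mean of its set's noiseless biological
intensities (a pooled aliquot) perturbed by its batch offset and
technical-only noise (`gis_noise_log2_sd = 0.1`, ~10% reporter CV); a
pooled standard re-measured in every batch has no biological spread, which
is why its noise is smaller than a biological channel's.

Missingness is **missing-not-at-random**: each cell is censored with
probability `expit(2.0 − 0.3·log2 x)`, so low-abundance measurements vanish
preferentially (~15–20% overall, concentrated in the bottom decile). The
mechanism and its parameters are an explicit assumption — intensity-based
proteomics only documents that zeros are missing, not the censoring law.

Traits (MoCA, CSF Aβ1-42/tTau/pTau181, plasma pTau181) are Gaussian per
set × diagnosis group with the emulated cohort's means and SDs, truncated
to physical ranges (MoCA ∈ [0, 30], concentrations > 0), and coupled at
ρ = 0.4 to a per-sample "signal score" (the standardized mean deviation of
the differential proteins), signed so that traits elevated in AD couple
positively. This makes protein–trait correlations detectable without
hard-coding them per protein. A 13-sample control overlap between sets is
available (`overlap_controls`) but off by default. One Set-2 control CSF
pTau181 parameter is a synthetic stand-in (source value unavailable),
chosen consistent with the neighboring cells.

**What the generator does not emulate:** peptide/spectrum-level structure
(co-isolation interference, ratio compression), non-Gaussian heavy-tailed
noise, shared-peptide protein inference artifacts, and real biological
covariance beyond the block-module structure. Passing tests therefore
demonstrate the pipeline's statistical machinery under the stated model,
not performance on real LC-MS data.

## Normalization

Channel-sum scaling computes `S_j` over the proteins observed in sample
*j* (a missing cell contributed no reporter intensity). "More than 50%
missing" is strict: a protein missing in exactly half the samples is kept.
The TMT path performs no imputation; the label-free path may impute
missing log2 values from `N(μ_j − 1.8σ_j, (0.3σ_j)²)` per sample (the
conventional downshift/width defaults, exposed in config).

## Batch harmonization

The ratio denominator is the intra-batch **GIS median** (the anchored
variant); with `use_gis=false` it falls back to the intra-batch all-sample
median. The two-way median polish sweeps columns first, then rows, folding
the running medians of the effect vectors into an overall term; the median
of an even count is the midpoint of the two central values (results depend
on this convention). Convergence is declared when no row or column effect
moves more than `tol = 1e-6` between sweeps (cap 100 sweeps; polish
converges in tens of sweeps, the cap guards cycling on ties).
Reconstruction keeps `residual + row effect + per-protein grand median`:
column effects are pure sample loading and are dropped; the grand median
preserves each protein's central tendency for concentration-rank analyses.

Covariate regression fits, per protein, OLS of abundance on protected
(diagnosis) plus unprotected terms on each of B = 200 sample-level
bootstrap resamples and takes the median coefficient; the corrected value
subtracts only the unprotected contributions, centered at the covariate
means. Proteins with fewer complete observations than model terms + 2 are
left uncorrected and flagged. Categorical covariates are one-hot coded
against the first (sorted) level.

## Differential testing and its calibration

The group test is the pooled-variance Student's *t* (Welch via
`equal_var=False`) on pairwise-complete observations, BH-adjusted within
each analysis table. A known property of any regress-then-test pipeline:
subtracting fitted covariate effects and then applying a t-test with
n₁+n₂−2 df overstates the degrees of freedom and inflates the type-I error
(the effect grows with the number of model terms and with
diagnosis–covariate collinearity; an independent statsmodels-based
reimplementation shows the same inflation). Calibration claims are
therefore made at the harmonized (pre-regression) stage, where measured
type-I error on the null block is ≈ 0.04–0.06 at α = 0.05; the regression
stage is kept for effect-size estimation, where it is unbiased.

## Meta-analysis and boundaries

Fisher's method is the default combiner (Stouffer's inverse-normal via
config); a single available p passes through; p = 0 is clamped to the
smallest positive float with a warning. AT+ boundaries: the tTau/Aβ1-42
ratio must **strictly** exceed 0.226 for AD (equality keeps a control);
MoCA exactly 24 satisfies both "AD ≤ 24" and "control ≥ 24", so the
diagnosis label decides. The Z-transform uses the sample (n−1) SD.
Overlapping control subjects are retained in meta-analysis and trait
correlation (the combined-p independence assumption is then mildly
violated, as in the emulated study) but deduplicated for ROC.

## Module projection and enrichment

Eigenproteins are the first right-singular vector of the z-scored member ×
sample matrix (missing values zero-filled after standardization), unit
norm, sign-oriented so the mean member correlation is positive (exact ties
align to the first member). bicor uses `u = (x − median)/(9·MAD)` with the
**raw** MAD (no 1.4826 consistency constant) and Tukey biweights
`(1−u²)²·1{|u|<1}`; zero-MAD vectors fall back to unweighted
mean-centering with a warning. No outlier-fraction capping is applied
(a config hook exists, off by default). Ties between modules at equal kME
break by label order and are flagged.

The enrichment Z-score is the standardized hypergeometric deviate
`Z = (k − nK/N) / sqrt(nK(N−K)(N−n)/(N²(N−1)))`, order-consistent with the
one-tailed FET p for fixed margins. Both the conventional Z > 1.96 and the
looser Z > 1.3 gates are config values, never hard-coded. Enrichment
backgrounds are explicit arguments because results are
background-sensitive.

A structural note on the kME ≥ 0.30 rule: the null kME has sd ≈ 1/√(n−3)
over n reference samples, so with 60 reference samples and 10 candidate
eigenproteins about 10% of unrelated proteins exceed 0.30 for at least one
module by chance (measured: ~10%; expected from the normal tail: ~11%).
The cutoff only isolates background cleanly when the reference cohort is
large (hundreds of samples, as in real consensus networks) or the module
count is small.

## Classification

The AUC is the Mann–Whitney pair-probability estimate (ties one half);
its variance and the correlated-AUC test use DeLong's placement-value
components, with 95% CIs as AUC ± 1.96·SE clipped to [0, 1]. Threshold
metrics are reported at every distinct cut with the Youden-optimal row
(max sens + spec − 1, ties to the lower threshold) marked. The logistic
fit is IRLS on internally standardized features (tol 1e-8 on the
log-likelihood, 100 iterations); perfect separation is flagged and the
last iterate's scores returned rather than silently diverging.
Single-marker AUCs below 0.5 are sign-flipped and flagged so ranking
reflects discriminative ability. Panels are fitted and evaluated
**in-sample** — with strong simulated effects the panel AUC saturates at
1.0 and is optimistic by construction; no cross-validation claim is made.
Single-marker ROC is invariant to the Z-transform; panels use Z-scored
inputs so coefficients are per-SD.

## Problem sizes used by the test suite

Oracle-equivalence checks enumerate all sorted 0.05-grid p-vectors up to
length 6 (~230k vectors; BH is permutation-equivariant, asserted
separately) and every hypergeometric margin configuration with N ≤ 60.
Recovery checks run the two-set design at 2000 proteins with 30+30 samples
per group per set and B = 50 bootstrap resamples (the regression median is
insensitive to B well below the production default of 200); module
recovery uses 2000 proteins, 10 modules, 60 reference samples; DeLong
calibration uses 1000 null replicates at n = 100. The acceptance script
runs the full study-scale design (18+18 and 36+49, B = 200) in under a
minute.

## Known limitations

- Regress-then-test df inflation (above); moderated or mixed-model tests
  are out of scope by design.
- In-sample panel evaluation; a CV mode would be an extension.
- The MNAR mechanism is assumed, not estimated from data.
- GIS-ratio harmonization injects the reference channel's technical noise
  into every sample of its batch; with one GIS per batch this slightly
  increases within-group variance (conservative for testing).
- Fisher combination treats the two sets as independent even when control
  subjects overlap (deduplication available via config).
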