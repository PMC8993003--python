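# Methods

This note documents the models, conventions and numerical choices
behind `ctprs`, in the spirit of a statistical package's methods
appendix. It states no empirical claim that the test suite or the
acceptance script does not itself compute.

## 1. The synthetic world

The simulator exists because the kind of cohort this pipeline targets —
school-based longitudinal samples with genotypes and a rare binary
outcome — is not publicly redistributable. It generates the *minimal*
statistical structure each downstream stage relies on, no more.

### Genotypes

Each of `n_blocks` LD blocks is an AR(1) latent Gaussian: haplotype
latents satisfy `z_k = rho z_{k-1} + sqrt(1-rho^2) e_k` within a block
and are independent across blocks and people. A haplotype carries the
effect allele when its latent exceeds `Phi^{-1}(1-f)` for the variant's
frequency `f ~ Uniform(maf_range)`; two haplotypes sum to a dosage in
{0,1,2}. This gives tunable, geometrically decaying pairwise dosage
r² — all that clumping and pruning need — while keeping dosages exactly
integer with no missingness. Block start positions are 5 Mb apart
(variants 1 kb apart within a block), so blocks can never interact
through the 2 Mb clumping window; inter-block independence is a design
guarantee, not a sampling accident.

What is *not* modeled: recombination hotspots, allele-frequency
divergence between populations, imputation uncertainty (no INFO
scores), relatedness, sex chromosomes. A green end-to-end test
establishes that the algorithms are correct under blocked stationary
LD, not that the pipeline is robust to real-data pathologies.

### Effects and the discovery GWAS

`round(pi_causal * m)` variants are causal; their effects are i.i.d.
`N(0, h2/n_causal)` per *standardized* dosage, so the genetic value
`g_i = sum_j beta_j z_ij` has variance `h2_discovery` in expectation
(exactly `h2` in expectation even under LD, because the latent
correlation matrix has unit diagonal). The discovery trait is
`y = g + e`, `Var(e) = 1 - h2`, and summary statistics are per-variant
simple linear regressions of `y` on raw dosage — deliberately marginal,
as in a real GWAS, so that LD leakage of effects onto non-causal
variants is present and clumping has something real to do.
Monomorphic variants are recorded with beta 0, p 1 rather than raised,
mirroring how association pipelines tolerate them.

### Target outcome

A liability-threshold model: `L = s * rg * g + e`, where `s = sex_gxe`
for males (prob. 0.45) and 1 for females, and `Var(e) = 1 - rg^2 h2`
makes female liability variance 1. The outcome is `L > t_sex` with
`t_sex` the per-sex Gaussian `(1 - prevalence)` quantile of that sex's
liability scale, keeping prevalence (default 0.076, the anchored
cohort's rate) equal across sexes; a sex main effect on prevalence is
deliberately not simulated so that interaction tests isolate the
slope modulation. The association stage still fits logistic models to
this liability-generated outcome — the same mild model mismatch a real
analysis lives with.

Defaults (`n_target=1103`, prevalence 0.076, 45% male, three cohort
labels, Bernoulli(0.5) intervention) mirror the emulated study design;
`rg`, `sex_gxe`, `h2_discovery`, `pi_causal` are simulation knobs with
defaults (1.0, 1.0, 0.3, 0.2) chosen to give a clearly detectable but
not degenerate signal at cohort scale.

## 2. Harmonization and QC conventions

* Variants match on id, falling back to chrom:pos. If the effect allele
  equals the genotype's other allele, dosages are recoded `2 - g`;
  unambiguous strand flips (complement matches) are resolved the same
  way; A/T and C/G palindromic variants are dropped by default
  (configurable) because strand cannot be determined without frequency
  heuristics, which we do not attempt.
* QC order: samples first (missingness > 0.10 removed), then variants
  on the retained samples — MAF < 0.01, missingness > 0.05, exact HWE
  p < 1e-4, and INFO < 0.8 when an INFO column exists. Each removed
  variant carries one primary reason, priority maf > missingness >
  hwe > info. Sample-first makes the variant statistics well-defined;
  applying the filter twice is a no-op (tested).
* MAF is computed from the target sample's non-missing dosages, never
  from the discovery frequency column.
* The HWE test is the exact conditional test (enumeration over all
  heterozygote counts compatible with the allele counts, summing
  probabilities ≤ the observed configuration's), computed in log space
  with a 1e-12 relative guard against float ties. Positions are 1-based
  throughout (VCF/BIM convention).

## 3. Clumping, pruning, PCA

* Clumping is greedy by ascending p (ties: chrom, pos, id — fully
  deterministic). The 2 Mb window is interpreted as a *radius*
  (|pos difference| ≤ 2e6), the dominant tool convention. Removal
  requires r² ≥ threshold, so the grid point r² = 1 removes only
  numerically perfect duplicates (within 1e-12).
* LD is the squared Pearson correlation of dosages over
  pairwise-complete samples; a monomorphic vector has undefined LD and
  is treated as unlinked (logged). LD is computed on the target
  dosages themselves; a reference panel can be substituted by passing
  its GenotypeMatrix.
* Pruning for the PCA input uses window 500 kb, step 50, r² 0.2
  (configurable; unstated in the emulated study, these are common
  defaults). Within a window the smaller-MAF member of an offending
  pair is dropped (ties: later position, then id).
* PCA standardizes dosages by `2f` and `sqrt(2f(1-f))` after mean
  imputation, then eigendecomposes the smaller Gram matrix; signs are
  fixed by making each component's largest-magnitude loading positive,
  so results are platform-reproducible.

## 4. Scoring and tuning

* Raw scores are weighted *sums* (not averages); standardization
  (n−1 denominator) makes the distinction immaterial downstream and
  gives the per-1-SD aOR interpretation.
* Missing dosages are imputed as `2f` from the target sample
  (mean imputation), the standard scoring convention.
* Grid cells with no passing variant are flagged empty and excluded
  from tuning rather than raised: a 5e-8 cell is legitimately empty at
  small discovery sizes.
* The tuning criterion is the AUC of a score-only logistic model
  (Nagelkerke increment over covariates available as `delta_r2`).
  Ties break toward (larger p threshold, then larger r²) — the less
  aggressive recipe. cv2 folds are outcome-stratified so both folds
  contain cases at 7.6% prevalence; out-of-fold scores are standardized
  with in-fold parameters to avoid leakage (tested by permuting
  out-fold outcomes under a fixed fold assignment).

## 5. Association and metrics

* Logistic fits use IRLS to a relative log-likelihood tolerance of
  1e-10 (max 100 iterations) with observed-information covariance.
  Rank deficiency is detected by pivoted QR before fitting and names a
  collinear column; separation raises an explicit error once fitted
  probabilities pin to 0/1 with diverging coefficients. statsmodels
  and a generic BFGS optimizer serve as independent cross-checks in the
  test suite, not as the implementation.
* CI: Wald on the log-odds scale with z = 1.959964.
* AUC is the Mann–Whitney form (ties counted 1/2). S80 takes, among
  thresholds achieving specificity ≥ 0.80, the most liberal one and
  returns its sensitivity — deterministic, no interpolation (an
  interpolating variant sits behind a flag).
* Pseudo-R² defaults to Nagelkerke (the PRS-literature convention);
  Cox–Snell and McFadden are available behind a flag. ΔR² is reported
  in percentage points: full model minus covariate-only model for main
  models, and minus the covariates+PRS model for interaction models
  (the increment attributable to the added term).
* Hosmer–Lemeshow uses g = 10 risk deciles with tied fitted
  probabilities kept in one group; groups with degenerate expectation
  merge into a neighbour with a df reduction and a warning. The
  statistic uses the `(O-E)^2 / (E(1-E/n_g))` form with a
  chi-square(g−2) reference.
* The cohort covariate is dummy-coded against its first (sorted)
  level; no multiple-testing adjustment is applied across scores,
  matching the emulated reporting style.

## 6. Power

The closed form `exp[(z_{1-a/2} + z_{power}) / sqrt(n p (1-p))]` is the
normal-approximation (Hsieh-style) detectable effect for a 1-SD
continuous predictor, chosen because the emulated analysis's power
method is unstated and this form reproduces its two sex-stratified
values at two decimals (the full-sample value computes to 1.37 against
a reported 1.38; no standard closed form we examined reproduces all
three simultaneously, and the package reports its honestly computed
value). The Monte-Carlo check simulates the actual Wald test with the
intercept solved by Gauss–Hermite quadrature plus Brent root-finding
(tolerance 1e-10) so the expected case count matches; non-convergent
replicates are excluded and counted, with a warning above 5%.

## 7. Known limitations

* One discovery trait per run: correlated multi-trait discovery (to
  mimic several PRS with known inter-score correlations) is not
  implemented.
* No reference-panel LD by default; no D′ or shrinkage LD estimators.
* No liftover, multi-allelic splitting, or dosage-field (DS) VCF
  support; PLINK1 but not PLINK2 binary formats.
* No Firth penalization: quasi-separated rare-outcome fits fail loudly
  instead of being shrunk.
* In-sample AUC/S80 for a given fitted model (cross-validated scores
  enter through the tuning stage, not through the metric itself).
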