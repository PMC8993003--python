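# ctprs

A clumping-and-thresholding (C+T) polygenic risk score pipeline for
binary outcomes, with a built-in synthetic-cohort simulator so every
stage can be exercised and validated without access to real genotype
data.

## Who this is for

Analysts studying whether polygenic liability for one trait (estimated
from an external discovery GWAS) predicts a binary outcome in a target
cohort — e.g. whether substance-use PRS are associated with a rare
misuse outcome in a longitudinal sample. The package covers the whole
workflow: reading summary statistics and genotypes, allele
harmonization, QC, LD clumping, grid scoring, hyperparameter tuning,
ancestry PCA, logistic association with the standard reporting metrics,
and a detectable-effect power analysis.

## The method

**Scoring.** For discovery effect sizes $\hat\beta_j$ and target
effect-allele dosages $g_{ij} \in \{0,1,2\}$, the score of person $i$ is

$$\mathrm{PRS}_i = \sum_{j \in S(r^2,\ p_T)} \hat\beta_j\, g_{ij},$$

where $S(r^2, p_T)$ is chosen by greedy LD clumping (visit variants by
ascending p-value; each index variant absorbs variants within a 2 Mb
window whose dosage correlation satisfies $r^2 \ge$ threshold) followed
by p-value thresholding ($\hat p_j \le p_T$). The grid crosses
$r^2 \in \{0.1, 0.2, 0.4, 0.6, 0.8, 1\}$ with
$p_T \in \{5\times10^{-1}, 5\times10^{-2}, 5\times10^{-4},
5\times10^{-6}, 5\times10^{-8}\}$ (30 cells).

**Tuning.** Either external-sample tuning (pick the cell maximizing AUC
on a tuning cohort, apply the recipe to the validation cohort) or
two-fold cross-validation (outcome-stratified halves; each half is
scored from the cell tuned on the other half, standardized with the
tuning half's parameters, so no sample influences its own score
recipe).

**Association.** Logistic regression of the outcome on the standardized
PRS with sex, intervention, cohort dummies and 10 genotype PCs as
covariates; reported per model: adjusted odds ratio with 95% Wald CI,
AUC, sensitivity at 80% specificity (S80), the Nagelkerke
pseudo-$R^2$ increment over the covariate-only model (in percentage
points), and the Hosmer–Lemeshow calibration test. Sex×PRS interaction
and sex-stratified variants are built in.

**Power.** The minimal detectable OR per 1 SD of predictor at
two-sided level $\alpha$ and power $1-\beta$ is
$\exp[(z_{1-\alpha/2} + z_{1-\beta}) / \sqrt{n\,\bar p(1-\bar p)}]$
with case fraction $\bar p$, cross-checked by direct Monte-Carlo
simulation of the Wald test.

**Simulator.** LD-blocked genotypes from a thresholded latent AR(1)
Gaussian (two haplotypes per person), a marginal-regression discovery
GWAS with chosen heritability and causal fraction, and a
liability-threshold binary target outcome with tunable genetic sharing
(`rg`), prevalence (default 7.6%) and a sex-modulated genetic effect
(`sex_gxe`). See `docs/methods.md` for assumptions and limitations.

## Worked example

Run the full synthetic pipeline end to end:

```bash
prs-pipeline run --out-dir run1 --seed 1
```

or in Python:

```python
from ctprs import PipelineConfig, SimConfig, run_pipeline
cfg = PipelineConfig(out_dir="run1",
                     sim=SimConfig(n_discovery=2000, n_target=1000,
                                   n_blocks=20, block_size=10, seed=1),
                     seed=1)
run_pipeline(cfg)
```

The run directory contains the simulated inputs (`sumstats.tsv`,
`target_dosages.tsv`, `pheno.tsv`), QC report, clump table, the 30-cell
score grid, PCs, cv2-tuned scores, association results and a manifest
with per-stage SHA-256 hashes. The fitted main model prints:

```
PRS: aOR = 3.06 (95% CI: 2.20, 4.24), p = 2.23e-11
AUC = 0.79   S80 = 0.61   delta R2 = 12.0%
Hosmer-Lemeshow: chi2 = 3.49, p = 0.900
```

With `h2_discovery=0.5` and full genetic sharing (`rg=1`) the simulated
PRS is strongly predictive: each SD of score triples the odds of the
outcome, discrimination rises well above the covariate-only model
(ΔR² ≈ 12 percentage points), and the calibration test shows no
misfit. `power.json` reports the minimal detectable OR for the
realized cohort — e.g. 1.39 for 79 cases among n = 1000 — computed with
the same closed form exposed by `prs-pipeline power`:

```bash
$ prs-pipeline power --n 494 --cases 40
detectable OR = 1.5874 (1.59 at 2 dp)
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch via the package's
closed-form power routine, the minimal detectable odds ratios for three
fixed sample configurations (n=1103/84 cases, n=494/40, n=609/44) and
writes them to JSON, alongside a printed Monte-Carlo cross-check of the
full-sample value:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
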