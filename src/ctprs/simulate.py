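"""Synthetic linked discovery/target cohorts for PRS pipeline testing.

The generator produces the statistical structure a clumping-and-
thresholding analysis assumes, without any external download:

* LD-blocked biallelic genotypes.  Each block is an AR(1) latent
  Gaussian — two independent haplotype draws per person, each haplotype
  carrying the alternate allele when its latent value exceeds the
  per-variant frequency quantile — so dosages live in {0, 1, 2} and the
  pairwise dosage correlation decays like ``rho**|i-j|`` within a block
  while blocks are independent and placed far apart (beyond any
  clumping window).
* A continuous discovery trait with heritability ``h2_discovery``
  concentrated in a random causal subset, and per-variant marginal
  regression summary statistics of that trait — the stand-in for a
  discovery GWAS.
* A binary target outcome from a liability-threshold model: liability
  is a genetic term shared with the discovery trait (scaled by ``rg``,
  and by ``sex_gxe`` in males) plus Gaussian noise, thresholded at the
  per-sex quantile that yields the requested prevalence (default 7.6%).

Genetic values are defined on standardized dosages (centered by ``2f``
and scaled by ``sqrt(2 f (1-f))``) so that the variance of the genetic
term equals the nominal heritability in expectation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError, GenotypeMatrix, PhenoTable, SummaryStats

__all__ = [
    "SimConfig",
    "EffectVector",
    "simulate_ld_genotypes",
    "simulate_effects",
    "simulate_discovery_sumstats",
    "simulate_target_cohort",
]

#: distance between consecutive block start positions; > 2 Mb clump window
_BLOCK_SPACING_BP = 5_000_000
#: spacing between adjacent variants inside a block
_INTRA_BLOCK_BP = 1_000


@dataclass
class SimConfig:
    """All knobs of the synthetic world, validated on construction.

    Parameters
    ----------
    n_discovery, n_target
        Sample sizes of the discovery GWAS and the target cohort.
    n_blocks, block_size
        LD structure: ``n_blocks`` independent blocks of ``block_size``
        variants each.
    rho
        Latent AR(1) correlation between adjacent variants in a block,
        in [0, 1).  0 gives independent variants.
    maf_range
        Per-variant minor-allele frequency drawn uniformly from this
        interval, bounds in (0, 0.5].
    pi_causal
        Fraction of variants carrying a true effect, in (0, 1].
    h2_discovery
        Heritability of the continuous discovery trait in [0, 1].
    rg
        Scaling of the discovery genetic value into the target
        liability, in [-1, 1]; 0 decouples the two traits.
    prevalence
        Target outcome prevalence in (0, 1); default 0.076.
    sex_gxe
        Multiplicative scaling of the genetic liability term in males
        relative to females (1 = no sex modulation), >= 0.
    seed
        Integer RNG seed; identical configs reproduce identical data.
    """

    n_discovery: int = 2000
    n_target: int = 1103
    n_blocks: int = 20
    block_size: int = 10
    rho: float = 0.6
    maf_range: tuple = (0.05, 0.5)
    pi_causal: float = 0.2
    h2_discovery: float = 0.3
    rg: float = 1.0
    prevalence: float = 0.076
    sex_gxe: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(name, msg):
            raise ConfigError(f"invalid SimConfig field {name!r}: {msg}")

        if self.n_discovery < 1:
            bad("n_discovery", "must be >= 1")
        if self.n_target < 1:
            bad("n_target", "must be >= 1")
        if self.n_blocks < 1 or self.block_size < 1:
            bad("n_blocks/block_size", "need n_blocks*block_size >= 1")
        if not 0 <= self.rho < 1:
            bad("rho", "must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            bad("maf_range", "bounds must satisfy 0 < lo <= hi <= 0.5")
        if not 0 < self.pi_causal <= 1:
            bad("pi_causal", "must lie in (0, 1]")
        if not 0 <= self.h2_discovery <= 1:
            bad("h2_discovery", "must lie in [0, 1]")
        if not -1 <= self.rg <= 1:
            bad("rg", "must lie in [-1, 1]")
        if not 0 < self.prevalence < 1:
            bad("prevalence", "must lie in (0, 1)")
        if self.sex_gxe < 0:
            bad("sex_gxe", "must be >= 0")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-specific generator derived from the master seed."""
        # crc32 is stable across processes, unlike built-in str hash
        key = zlib.crc32(stage.encode()) % (2**31)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class EffectVector:
    """True per-variant effects on the liability/trait scale.

    ``beta`` is the effect per standardized-dosage unit; non-causal
    entries are exactly zero.
    """

    beta: np.ndarray
    causal: np.ndarray  # boolean mask

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.causal = np.asarray(self.causal, dtype=bool)
        if self.beta.shape != self.causal.shape:
            raise ConfigError("beta and causal must have equal length")
        if np.any(self.beta[~self.causal] != 0):
            raise ConfigError("non-causal effects must be exactly zero")


def _variant_metadata(config: SimConfig) -> pd.DataFrame:
    m = config.n_variants
    block = np.repeat(np.arange(config.n_blocks), config.block_size)
    within = np.tile(np.arange(config.block_size), config.n_blocks)
    pos = 1 + block * _BLOCK_SPACING_BP + within * _INTRA_BLOCK_BP
    return pd.DataFrame(
        {
            "id": [f"rs{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": pos.astype(int),
            "allele_a": "A",
            "allele_b": "G",
        }
    )


def simulate_ld_genotypes(
    config: SimConfig, n: int, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw an ``n`` x ``n_variants`` dosage matrix with block-AR(1) LD.

    Each haplotype's latent vector follows ``z_k = rho z_{k-1} +
    sqrt(1-rho^2) eps_k`` within a block; the haplotype carries the
    alternate allele when ``z > Phi^{-1}(1-f)`` for the variant's drawn
    frequency ``f``.  Two haplotypes sum to the dosage, so dosages are
    in {0, 1, 2} with no missingness.
    """
    if n < 1:
        raise ConfigError("invalid sample count: n must be >= 1")
    if rng is None:
        rng = config.rng("genotypes")
    m = config.n_variants
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    thresh = stats.norm.ppf(1 - freqs)

    dosage = np.zeros((n, m), dtype=float)
    for _hap in range(2):
        latent = np.empty((n, m))
        for b in range(config.n_blocks):
            sl = slice(b * config.block_size, (b + 1) * config.block_size)
            eps = rng.standard_normal((n, config.block_size))
            z = np.empty_like(eps)
            z[:, 0] = eps[:, 0]
            scale = np.sqrt(1 - config.rho**2)
            for k in range(1, config.block_size):
                z[:, k] = config.rho * z[:, k - 1] + scale * eps[:, k]
            latent[:, sl] = z
        dosage += (latent > thresh).astype(float)

    geno = GenotypeMatrix(
        sample_ids=np.array([f"S{i + 1}" for i in range(n)], dtype=object),
        variants=_variant_metadata(config),
        dosages=dosage,
    )
    return geno


def simulate_effects(
    config: SimConfig, m: int, rng: np.random.Generator | None = None
) -> EffectVector:
    """Choose causal variants and draw their effect sizes.

    ``round(pi_causal*m)`` variants are causal; their effects are i.i.d.
    normal with variance ``h2_discovery / n_causal`` so the standardized
    genetic value has variance ``h2_discovery`` in expectation.
    """
    if m != config.n_variants:
        raise ConfigError(
            f"m={m} does not equal n_blocks*block_size={config.n_variants}"
        )
    n_causal = int(round(config.pi_causal * m))
    if n_causal < 1:
        raise ConfigError("pi_causal*m < 1: no causal variants possible")
    if rng is None:
        rng = config.rng("effects")
    idx = rng.choice(m, size=n_causal, replace=False)
    beta = np.zeros(m)
    causal = np.zeros(m, dtype=bool)
    causal[idx] = True
    if config.h2_discovery > 0:
        beta[idx] = rng.normal(0.0, np.sqrt(config.h2_discovery / n_causal), n_causal)
    return EffectVector(beta=beta, causal=causal)


def _standardized_dosages(geno: GenotypeMatrix) -> np.ndarray:
    """Center by 2f and scale by sqrt(2f(1-f)); monomorphic columns -> 0."""
    f = geno.allele_freq()
    sd = np.sqrt(2 * f * (1 - f))
    poly = sd > 0
    z = (geno.dosages - 2 * f) / np.where(poly, sd, 1.0)
    if not poly.all():
        z[:, ~poly] = 0.0
    return z


def genetic_values(geno: GenotypeMatrix, effects: EffectVector) -> np.ndarray:
    """True genetic value per sample: standardized dosages times beta."""
    return _standardized_dosages(geno) @ effects.beta


def simulate_discovery_sumstats(
    geno: GenotypeMatrix,
    effects: EffectVector,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SummaryStats:
    """Marginal-regression GWAS of a simulated continuous trait.

    The trait is ``y = g + e`` with ``g`` the standardized genetic value
    and ``Var(e) = 1 - h2_discovery``.  Each variant is tested with a
    simple linear regression of ``y`` on its raw dosage; the effect
    allele is the dosage-counted allele.  Monomorphic variants are
    recorded with beta 0 and p 1 rather than failing.
    """
    if rng is None:
        rng = config.rng("discovery-trait")
    n = geno.n_samples
    g = genetic_values(geno, effects)
    e_sd = np.sqrt(max(1.0 - config.h2_discovery, 0.0))
    y = g + rng.normal(0.0, 1.0, n) * e_sd

    X = geno.dosages
    xm = X.mean(axis=0)
    xc = X - xm
    sxx = (xc**2).sum(axis=0)
    yc = y - y.mean()
    sxy = xc.T @ yc
    poly = sxx > 0
    beta = np.zeros(X.shape[1])
    pval = np.ones(X.shape[1])
    beta[poly] = sxy[poly] / sxx[poly]
    if n > 2:
        resid_ss = (yc**2).sum() - beta[poly] * sxy[poly]
        resid_ss = np.maximum(resid_ss, 0.0)
        se = np.sqrt(resid_ss / (n - 2) / sxx[poly])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta[poly] / se, np.inf)
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        pval[poly] = np.clip(p, np.nextafter(0, 1), 1.0)

    table = geno.variants.copy()
    table = table.rename(columns={"allele_a": "effect_allele", "allele_b": "other_allele"})
    table["beta"] = beta
    table["p"] = pval
    table["freq"] = geno.allele_freq()
    return SummaryStats(table[[
        "id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p", "freq"
    ]])


def simulate_target_cohort(
    geno: GenotypeMatrix,
    effects: EffectVector,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> PhenoTable:
    """Liability-threshold binary outcome plus covariates for the target.

    Liability is ``s * rg * g + e`` with ``s = sex_gxe`` for males and 1
    for females, ``g`` the standardized genetic value, and ``e`` scaled
    so total liability variance is 1 in females.  The outcome threshold
    is the per-sex ``(1-prevalence)`` Gaussian quantile of each sex's
    liability scale, keeping prevalence equal across sexes.
    """
    if rng is None:
        rng = config.rng("target-cohort")
    n = geno.n_samples
    g = genetic_values(geno, effects)
    sex = (rng.uniform(size=n) < 0.45).astype(int)  # 1 = male, ~45% male

    gvar = config.rg**2 * config.h2_discovery
    e_sd = np.sqrt(max(1.0 - gvar, 0.0))
    s = np.where(sex == 1, config.sex_gxe, 1.0)
    liability = s * config.rg * g + rng.normal(0.0, 1.0, n) * e_sd

    # per-sex liability SD under the model; threshold at the (1-K) quantile
    sd_by_sex = np.sqrt(s**2 * gvar + e_sd**2)
    thresh = sd_by_sex * stats.norm.ppf(1 - config.prevalence)
    outcome = (liability > thresh).astype(int)

    table = pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "outcome": outcome,
            "sex": sex,
            "intervention": rng.integers(0, 2, n),
            "cohort": rng.integers(1, 4, n).astype(str),
        }
    )
    return PhenoTable(table)
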