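"""Core in-memory containers shared by every pipeline stage.

The three tables mirror the files a PRS analysis moves between tools:
discovery summary statistics (per-variant weights), a target genotype
matrix (effect-allele dosages), and a phenotype/covariate table.  All of
them are thin, validated wrappers around pandas/numpy objects so that
downstream stages can rely on their invariants instead of re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStats",
    "GenotypeMatrix",
    "PhenoTable",
    "FormatError",
    "ConfigError",
]

_VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file or table violates its format contract."""


class ConfigError(ValueError):
    """Raised when a configuration field is out of its allowed range."""


@dataclass
class SummaryStats:
    """Per-variant discovery GWAS effects used as PRS weights.

    ``table`` columns: ``id, chrom, pos, effect_allele, other_allele,
    beta, p`` plus optional ``freq`` (effect-allele frequency) and
    ``info`` (imputation quality).  ``beta`` is the effect per copy of
    the effect allele on whatever scale the discovery GWAS used;
    ``p`` is the two-sided marginal p-value.
    """

    table: pd.DataFrame

    REQUIRED = ("id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"summary statistics missing column(s): {missing}")
        self.validate()

    def validate(self) -> None:
        df = self.table
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise FormatError(f"duplicate variant id in summary statistics: {dup!r}")
        p = df["p"].to_numpy(float)
        if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
            raise FormatError("summary statistics contain p outside (0, 1]")
        if (df["pos"].to_numpy() < 1).any():
            raise FormatError("summary statistics contain pos < 1")
        same = (df["effect_allele"] == df["other_allele"]).to_numpy()
        if same.any():
            raise FormatError("effect_allele equals other_allele for some variants")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def subset(self, ids) -> "SummaryStats":
        keep = self.table["id"].isin(set(ids))
        return SummaryStats(self.table.loc[keep].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix.

    ``dosages`` holds values in {0, 1, 2} counted toward ``allele_a`` of
    each variant, with ``np.nan`` for missing genotypes.  ``variants``
    columns: ``id, chrom, pos, allele_a, allele_b``.
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise FormatError(
                f"dosage rows ({n}) != number of sample ids ({len(self.sample_ids)})"
            )
        if m != len(self.variants):
            raise FormatError(
                f"dosage columns ({m}) != number of variants ({len(self.variants)})"
            )
        if self.variants["id"].duplicated().any():
            raise FormatError("duplicate variant ids in genotype matrix")
        d = self.dosages
        ok = np.isnan(d) | (d == 0.0) | (d == 1.0) | (d == 2.0)
        if not ok.all():
            raise FormatError("dosages must be in {0, 1, 2} or missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Allele-a frequency from non-missing dosages (nan if all missing)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_rate_variants(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def missing_rate_samples(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def subset_variants(self, col_idx) -> "GenotypeMatrix":
        col_idx = np.asarray(col_idx)
        return GenotypeMatrix(
            self.sample_ids,
            self.variants.iloc[col_idx].reset_index(drop=True),
            self.dosages[:, col_idx],
        )

    def subset_samples(self, row_idx) -> "GenotypeMatrix":
        row_idx = np.asarray(row_idx)
        return GenotypeMatrix(
            self.sample_ids[row_idx],
            self.variants,
            self.dosages[row_idx, :],
        )


@dataclass
class PhenoTable:
    """Per-sample outcome, covariates and optional ancestry PCs.

    ``table`` columns: ``sample_id, outcome, sex, intervention, cohort``
    and any number of ``PC1..PCk`` columns.  ``outcome`` is the binary
    endpoint (1 = event), ``sex`` is 0 = female / 1 = male.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "outcome", "sex", "intervention", "cohort")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"phenotype table missing column(s): {missing}")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in phenotype table")
        for col in ("outcome", "sex", "intervention"):
            vals = set(pd.unique(df[col]))
            if not vals <= {0, 1}:
                raise FormatError(f"phenotype column {col!r} must be binary 0/1")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pc_columns(self) -> list:
        cols = [c for c in self.table.columns if c.startswith("PC") and c[2:].isdigit()]
        return sorted(cols, key=lambda c: int(c[2:]))

    def aligned_to(self, sample_ids) -> "PhenoTable":
        """Reorder rows to match ``sample_ids`` exactly (error on mismatch)."""
        df = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise FormatError(f"phenotype table missing sample(s): {missing[:5]}")
        out = df.loc[list(sample_ids)].reset_index()
        return PhenoTable(out)
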