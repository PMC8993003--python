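import numpy as np
import pandas as pd
import pytest

from ctprs.containers import GenotypeMatrix, PhenoTable, SummaryStats


def make_geno(dosages, positions=None, chrom="1", ids=None, alleles=("A", "G")):
    """Build a GenotypeMatrix from a plain dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if ids is None:
        ids = [f"rs{j + 1}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "id": ids,
            "chrom": chrom,
            "pos": positions,
            "allele_a": alleles[0],
            "allele_b": alleles[1],
        }
    )
    return GenotypeMatrix(
        np.array([f"S{i + 1}" for i in range(n)], dtype=object), variants, dosages
    )


def make_sumstats(ids, betas, ps, positions=None, chrom="1",
                  effect="A", other="G"):
    m = len(ids)
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    return SummaryStats(
        pd.DataFrame(
            {
                "id": ids,
                "chrom": chrom,
                "pos": positions,
                "effect_allele": effect,
                "other_allele": other,
                "beta": betas,
                "p": ps,
            }
        )
    )


def make_pheno(outcome, sex=None, rng=None, pcs=None):
    outcome = np.asarray(outcome, dtype=int)
    n = len(outcome)
    rng = rng or np.random.default_rng(0)
    if sex is None:
        sex = rng.integers(0, 2, n)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1}" for i in range(n)],
            "outcome": outcome,
            "sex": np.asarray(sex, dtype=int),
            "intervention": rng.integers(0, 2, n),
            "cohort": rng.integers(1, 4, n).astype(str),
        }
    )
    if pcs is not None:
        for k in range(pcs.shape[1]):
            df[f"PC{k + 1}"] = pcs[:, k]
    return PhenoTable(df)


@pytest.fixture
def toy_geno():
    return make_geno([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
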