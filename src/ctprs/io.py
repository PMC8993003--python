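"""File formats, allele harmonization and genotype quality control.

Readers accept the community formats a PRS workflow meets in practice —
summary-statistics TSV with a configurable column map, genotypes as VCF
(GT-based), PLINK1 .bed/.bim/.fam, or a plain dosage TSV — and writers
emit the same formats so synthetic cohorts round-trip.  Harmonization
aligns effect alleles between summary statistics and target genotypes
(allele swaps, strand flips, ambiguous-variant removal) and the QC stage
applies the standard sample/variant filters (sample missingness, MAF,
variant missingness, exact Hardy-Weinberg test, optional INFO score).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FormatError, GenotypeMatrix, PhenoTable, SummaryStats

log = logging.getLogger(__name__)

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "write_plink1",
    "read_pheno",
    "write_pheno",
    "harmonize",
    "hwe_exact_test",
    "qc_filter",
    "QCThresholds",
    "QCReport",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_SUMSTATS_COLUMNS = {
    "id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "p": "P",
    "freq": "FRQ",
    "info": "INFO",
}


# ---------------------------------------------------------------------------
# summary statistics


def read_sumstats(path, column_map: dict | None = None) -> SummaryStats:
    """Read a summary-statistics TSV into a validated :class:`SummaryStats`.

    ``column_map`` maps internal names (``id, chrom, pos, effect_allele,
    other_allele, beta, p`` and optional ``freq, info, or_``) to file
    column names; defaults to the PLINK-style header ``SNP CHR BP A1 A2
    BETA P``.  If the map supplies ``or_`` instead of ``beta`` the
    odds-ratio column is log-transformed.  Rows violating the invariants
    (p outside (0,1], identical alleles, duplicate ids) are dropped with
    a logged count; zero surviving rows is an error.
    """
    cmap = dict(DEFAULT_SUMSTATS_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cmap["chrom"]: str})

    has_or = "or_" in cmap and cmap["or_"] in df.columns
    mandatory = ["id", "chrom", "pos", "effect_allele", "other_allele", "p"]
    if not has_or:
        mandatory.append("beta")
    for key in mandatory:
        if cmap[key] not in df.columns:
            raise FormatError(f"summary statistics file missing column {cmap[key]!r}")

    out = pd.DataFrame(
        {
            "id": df[cmap["id"]].astype(str),
            "chrom": df[cmap["chrom"]].astype(str),
            "pos": df[cmap["pos"]].astype(int),
            "effect_allele": df[cmap["effect_allele"]].astype(str).str.upper(),
            "other_allele": df[cmap["other_allele"]].astype(str).str.upper(),
            "p": df[cmap["p"]].astype(float),
        }
    )
    if has_or:
        out["beta"] = np.log(df[cmap["or_"]].astype(float))
    else:
        out["beta"] = df[cmap["beta"]].astype(float)
    for opt in ("freq", "info"):
        if cmap.get(opt) in df.columns:
            out[opt] = df[cmap[opt]].astype(float)

    n0 = len(out)
    ok = (
        (out["p"] > 0)
        & (out["p"] <= 1)
        & np.isfinite(out["p"])
        & np.isfinite(out["beta"])
        & (out["pos"] >= 1)
        & (out["effect_allele"] != out["other_allele"])
        & ~out["id"].duplicated(keep="first")
    )
    out = out.loc[ok].reset_index(drop=True)
    if n0 - len(out):
        log.warning("read_sumstats: dropped %d invalid row(s)", n0 - len(out))
    if not len(out):
        raise FormatError("summary statistics file has zero valid rows")
    cols = ["id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p"]
    cols += [c for c in ("freq", "info") if c in out.columns]
    return SummaryStats(out[cols])


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write the standard TSV: SNP CHR BP A1 A2 BETA P [FRQ INFO]."""
    inv = {v: k for k, v in DEFAULT_SUMSTATS_COLUMNS.items()}
    df = ss.table.rename(columns={k: v for v, k in inv.items()})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF, PLINK1 .bed or dosage TSV.

    The format is auto-detected from the extension unless ``format``
    (``"vcf" | "bed" | "tsv"``) forces it.  Dosages are counted toward
    the recorded ``allele_a``: the ALT allele for VCF, the .bim
    allele-1 for PLINK1, and the ``allele_a`` column of a dosage TSV.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".vcf": "vcf", ".bed": "bed", ".tsv": "tsv", ".txt": "tsv"}.get(suffix)
        if format is None and path.name.endswith(".vcf.gz"):
            format = "vcf"
        if format is None:
            raise FormatError(f"cannot detect genotype format from {path.name!r}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "bed":
        return _read_plink1(path)
    if format == "tsv":
        return _read_dosage_tsv(path)
    raise FormatError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = np.asarray(vcf.samples, dtype=object)
    rows, recs = [], []
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            raise FormatError(f"non-biallelic record at VCF line for {v.ID or v.POS}")
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        gt = v.gt_types.astype(float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        recs.append(
            {
                "id": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": str(v.CHROM),
                "pos": int(v.POS),
                "allele_a": v.ALT[0],
                "allele_b": v.REF,
            }
        )
    if not recs:
        raise FormatError(f"no variant records in {path}")
    return GenotypeMatrix(sample_ids, pd.DataFrame(recs), np.asarray(rows).T)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT fields (REF=allele_b, ALT=allele_a)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.sample_ids))
            + "\n"
        )
        gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, var in geno.variants.iterrows():
            col = geno.dosages[:, j]
            gts = "\t".join(
                "./." if np.isnan(d) else gt_strings[d] for d in col
            )
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.id}\t{var.allele_b}\t{var.allele_a}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["id", "chrom", "pos", "allele_a", "allele_b"]
    for c in meta_cols:
        if c not in df.columns:
            raise FormatError(f"dosage TSV missing column {c!r}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise FormatError("dosage TSV has no sample columns")
    dosages = df[sample_cols].to_numpy(float).T
    return GenotypeMatrix(
        np.asarray(sample_cols, dtype=object), df[meta_cols].copy(), dosages
    )


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    body = pd.DataFrame(
        geno.dosages.T, columns=[str(s) for s in geno.sample_ids]
    )
    df = pd.concat([geno.variants.reset_index(drop=True), body], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _read_plink1(bed_path) -> GenotypeMatrix:
    """PLINK1 SNP-major .bed with its .bim/.fam companions."""
    bed_path = Path(bed_path)
    bim = pd.read_csv(
        bed_path.with_suffix(".bim"),
        sep=r"\s+",
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(
        bed_path.with_suffix(".fam"),
        sep=r"\s+",
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise FormatError(f"{bed_path} is not a PLINK1 .bed file (bad magic)")
    if raw[2] != 0x01:
        raise FormatError("only SNP-major PLINK1 .bed files are supported")
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_variant * m:
        raise FormatError(
            f"{bed_path}: expected {bytes_per_variant * m} data bytes, got {body.size}"
        )
    body = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11  # (m, bpv, 4)
    codes = codes.reshape(m, -1)[:, :n]
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    dosage = np.empty(codes.shape, dtype=float)
    dosage[codes == 0] = 2.0
    dosage[codes == 2] = 1.0
    dosage[codes == 3] = 0.0
    dosage[codes == 1] = np.nan
    variants = pd.DataFrame(
        {
            "id": bim["id"].astype(str),
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(int),
            "allele_a": bim["a1"],
            "allele_b": bim["a2"],
        }
    )
    return GenotypeMatrix(fam["iid"].to_numpy(object), variants, dosage.T)


def write_plink1(geno: GenotypeMatrix, prefix) -> None:
    """Write .bed/.bim/.fam (SNP-major) with allele-1 = allele_a."""
    prefix = Path(prefix)
    bim = geno.variants
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, v in bim.iterrows():
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.allele_a}\t{v.allele_b}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in geno.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    n, m = geno.dosages.shape
    code_of = {2.0: 0, 1.0: 2, 0.0: 3}
    bytes_per_variant = (n + 3) // 4
    codes = np.full((m, bytes_per_variant * 4), 1, dtype=np.uint8)  # 1 = missing pad
    for j in range(m):
        col = geno.dosages[:, j]
        cj = np.array(
            [1 if np.isnan(d) else code_of[d] for d in col], dtype=np.uint8
        )
        codes[j, :n] = cj
        codes[j, n:] = 0  # PLINK pads trailing slots with zero bits
    packed = (
        codes.reshape(m, bytes_per_variant, 4) << (np.arange(4) * 2)[None, None, :]
    ).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# phenotypes


def read_pheno(path) -> PhenoTable:
    df = pd.read_csv(path, sep="\t", dtype={"IID": str, "COHORT": str})
    rename = {
        "IID": "sample_id",
        "OUTCOME": "outcome",
        "OPIOID": "outcome",
        "SEX": "sex",
        "INTERVENTION": "intervention",
        "COHORT": "cohort",
    }
    df = df.rename(columns={c: rename[c] for c in df.columns if c in rename})
    return PhenoTable(df)


def write_pheno(pheno: PhenoTable, path) -> None:
    df = pheno.table.rename(
        columns={
            "sample_id": "IID",
            "outcome": "OPIOID",
            "sex": "SEX",
            "intervention": "INTERVENTION",
            "cohort": "COHORT",
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization


def _is_ambiguous(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a) == b


def harmonize(
    ss: SummaryStats,
    geno: GenotypeMatrix,
    drop_ambiguous: bool = True,
):
    """Align summary-statistic effect alleles with genotype dosages.

    Variants are matched on id with a chrom:pos fallback.  When the
    effect allele is the genotype's ``allele_b`` the dosage column is
    recoded ``2 - g``; unambiguous strand flips (A<->T, C<->G
    complements) are resolved the same way; ambiguous A/T and C/G
    variants are dropped when ``drop_ambiguous`` (default).  Returns the
    aligned ``(SummaryStats, GenotypeMatrix, report)`` triple where both
    outputs list the same variants in the same order.
    """
    gvar = geno.variants
    by_id = {vid: j for j, vid in enumerate(gvar["id"])}
    by_pos = {}
    for j, (c, p) in enumerate(zip(gvar["chrom"], gvar["pos"])):
        by_pos.setdefault((str(c), int(p)), j)

    ss_keep, g_cols, flip_cols = [], [], []
    report = {"matched": 0, "flipped": 0, "strand_resolved": 0,
              "ambiguous_dropped": [], "unmatched_dropped": [],
              "allele_mismatch_dropped": []}
    for i, row in ss.table.iterrows():
        j = by_id.get(row["id"])
        if j is None:
            j = by_pos.get((str(row["chrom"]), int(row["pos"])))
        if j is None:
            report["unmatched_dropped"].append(row["id"])
            continue
        ea, oa = row["effect_allele"], row["other_allele"]
        ga, gb = gvar.at[j, "allele_a"], gvar.at[j, "allele_b"]
        if _is_ambiguous(ea, oa) and drop_ambiguous:
            report["ambiguous_dropped"].append(row["id"])
            continue
        flip = None
        if (ea, oa) == (ga, gb):
            flip = False
        elif (ea, oa) == (gb, ga):
            flip = True
        else:
            cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
            if (cea, coa) == (ga, gb):
                flip = False
                report["strand_resolved"] += 1
            elif (cea, coa) == (gb, ga):
                flip = True
                report["strand_resolved"] += 1
        if flip is None:
            report["allele_mismatch_dropped"].append(row["id"])
            continue
        ss_keep.append(i)
        g_cols.append(j)
        flip_cols.append(flip)
        report["matched"] += 1
        report["flipped"] += int(flip)

    if not ss_keep:
        raise FormatError("harmonize: zero overlapping variants")

    ss_out = ss.table.iloc[ss_keep].reset_index(drop=True)
    g_out = geno.subset_variants(np.asarray(g_cols))
    flip_arr = np.asarray(flip_cols)
    if flip_arr.any():
        dos = g_out.dosages.copy()
        dos[:, flip_arr] = 2.0 - dos[:, flip_arr]
        var = g_out.variants.copy()
        a = var.loc[flip_arr, "allele_a"].copy()
        var.loc[flip_arr, "allele_a"] = var.loc[flip_arr, "allele_b"]
        var.loc[flip_arr, "allele_b"] = a
        g_out = GenotypeMatrix(g_out.sample_ids, var, dos)
    # after any strand resolution, record alleles on the sumstats strand
    g_out.variants["allele_a"] = ss_out["effect_allele"].to_numpy()
    g_out.variants["allele_b"] = ss_out["other_allele"].to_numpy()
    return SummaryStats(ss_out), g_out, report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Enumerates every heterozygote count consistent with the observed
    allele counts and sums the probabilities of configurations no more
    likely than the observed one (the standard exact formulation).
    Returns 1.0 for monomorphic or empty input.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_a = 2 * n_AA + n_Aa  # rarer-or-not allele count, symmetric below
    n_b = 2 * n_aa + n_Aa
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    # log-probability of each possible het count, same parity as `rare`
    from scipy.special import gammaln

    hets = np.arange(rare % 2, rare + 1, 2)
    logp = (
        hets * math.log(2)
        + gammaln(n + 1)
        - gammaln((rare - hets) // 2 + 1)
        - gammaln(hets + 1)
        - gammaln((2 * n - rare - hets) // 2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.searchsorted(hets, n_Aa)
    p_obs = probs[obs]
    # tolerance guards against float ties just above p_obs
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCThresholds:
    """Sample/variant filter thresholds (defaults follow array-QC convention)."""

    mind: float = 0.10       # max per-sample missing fraction
    maf: float = 0.01        # min minor-allele frequency
    geno_miss: float = 0.05  # max per-variant missing fraction
    hwe_p: float = 1e-4      # min exact HWE p-value
    info: float = 0.8        # min imputation INFO (applied only if present)


@dataclass
class QCReport:
    samples_removed: list = field(default_factory=list)  # (id, reason)
    variants_removed: list = field(default_factory=list)  # (id, reason)
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def summary(self) -> str:
        return (
            f"QC: removed {len(self.samples_removed)} sample(s), "
            f"{len(self.variants_removed)} variant(s) "
            f"[mind>{self.thresholds.mind}, maf<{self.thresholds.maf}, "
            f"miss>{self.thresholds.geno_miss}, hwe<{self.thresholds.hwe_p}, "
            f"info<{self.thresholds.info}]"
        )


def qc_filter(
    geno: GenotypeMatrix,
    ss: SummaryStats | None = None,
    thresholds: QCThresholds | None = None,
):
    """Apply sample filters first, then variant filters on retained samples.

    Samples exceeding the ``mind`` missing fraction are removed; then
    variants failing MAF, missingness, exact-HWE or (when an ``info``
    column is present in ``ss``) the INFO threshold are removed, each
    with a single primary reason in priority order maf > missingness >
    hwe > info.  Returns ``(geno, ss, report)`` with ``ss`` filtered to
    the surviving variants when supplied.
    """
    thr = thresholds or QCThresholds()
    report = QCReport(thresholds=thr)

    smiss = geno.missing_rate_samples()
    keep_s = smiss <= thr.mind
    for sid in geno.sample_ids[~keep_s]:
        report.samples_removed.append((sid, "missingness"))
    if not keep_s.any():
        raise FormatError("qc_filter: all samples removed")
    geno = geno.subset_samples(np.where(keep_s)[0])

    freq = geno.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    vmiss = geno.missing_rate_variants()
    info = None
    if ss is not None and "info" in ss.table.columns:
        info_map = dict(zip(ss.table["id"], ss.table["info"]))
        info = np.array([info_map.get(v, np.nan) for v in geno.variants["id"]])

    keep_v = np.ones(geno.n_variants, dtype=bool)
    for j, vid in enumerate(geno.variants["id"]):
        col = geno.dosages[:, j]
        obs = col[~np.isnan(col)]
        if np.isnan(maf[j]) or maf[j] < thr.maf:
            reason = "maf"
        elif vmiss[j] > thr.geno_miss:
            reason = "missingness"
        else:
            n_AA = int((obs == 2).sum())
            n_Aa = int((obs == 1).sum())
            n_aa = int((obs == 0).sum())
            if hwe_exact_test(n_AA, n_Aa, n_aa) < thr.hwe_p:
                reason = "hwe"
            elif info is not None and not np.isnan(info[j]) and info[j] < thr.info:
                reason = "info"
            else:
                continue
        keep_v[j] = False
        report.variants_removed.append((vid, reason))

    if not keep_v.any():
        raise FormatError("qc_filter: all variants removed")
    geno = geno.subset_variants(np.where(keep_v)[0])
    if ss is not None:
        ss = ss.subset(geno.variants["id"])
    return geno, ss, report
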