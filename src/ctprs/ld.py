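"""Pairwise LD, greedy p-value-ordered clumping, and window pruning.

LD between two variants is the squared Pearson correlation of their
dosages over pairwise-complete samples.  Clumping walks variants in
ascending p-value order, keeps each as an index, and absorbs every
not-yet-assigned variant on the same chromosome within the base-pair
window whose r-squared with the index reaches the threshold — the
classic PLINK semantics.  Pruning is the sliding-window variant used to
prepare the PCA input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix, SummaryStats

log = logging.getLogger(__name__)

__all__ = ["ClumpSpec", "ClumpResult", "ld_r2", "clump", "prune", "R2_GRID"]

#: the r-squared grid the score stage iterates over
R2_GRID = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0)

#: at threshold 1.0 only numerically perfect LD removes a companion
_PERFECT_LD_TOL = 1e-12


@dataclass
class ClumpSpec:
    r2_threshold: float
    window_bp: int = 2_000_000

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class ClumpResult:
    index_variants: list           # retained ids, ascending p
    removed: dict = field(default_factory=dict)  # removed id -> absorbing index id
    spec: ClumpSpec | None = None


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Uses pairwise-complete observations; a monomorphic vector has
    undefined LD and is reported as 0.0 with a log note (callers treat
    it as unlinked).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    x, y = g1[ok], g2[ok]
    if x.size < 2:
        raise ValueError("need >= 2 pairwise-complete observations")
    if x.std() == 0 or y.std() == 0:
        log.debug("ld_r2: monomorphic vector, treating r2 as 0")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_with_index(dos: np.ndarray, idx: int, cols: np.ndarray) -> np.ndarray:
    """Vectorised r2 between column `idx` and each column in `cols`."""
    x = dos[:, idx]
    out = np.empty(len(cols))
    Y = dos[:, cols]
    both = ~np.isnan(x)[:, None] & ~np.isnan(Y)
    if not np.isnan(dos).any():
        xm = x - x.mean()
        Ym = Y - Y.mean(axis=0)
        denom = np.sqrt((xm**2).sum() * (Ym**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, xm @ Ym / np.where(denom > 0, denom, 1.0), 0.0)
        return r**2
    for k in range(len(cols)):
        m = both[:, k]
        xs, ys = x[m], Y[m, k]
        if xs.size < 2 or xs.std() == 0 or ys.std() == 0:
            out[k] = 0.0
        else:
            out[k] = np.corrcoef(xs, ys)[0, 1] ** 2
    return out


def clump(ss: SummaryStats, geno: GenotypeMatrix, spec: ClumpSpec) -> ClumpResult:
    """Greedy p-value-ordered clumping of harmonized inputs.

    Variants are visited by ascending p (ties broken by chrom, pos, id);
    the current variant becomes an index and absorbs every unassigned
    variant on its chromosome within ``window_bp`` whose dosage
    r-squared with it is >= ``r2_threshold``.  At threshold 1.0 only
    perfect LD (within 1e-12) absorbs.
    """
    df = ss.table
    if not len(df):
        return ClumpResult(index_variants=[], removed={}, spec=spec)
    order = df.sort_values(["p", "chrom", "pos", "id"], kind="mergesort").index.to_numpy()
    gidx = {vid: j for j, vid in enumerate(geno.variants["id"])}
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(int)
    ids = df["id"].to_numpy()

    cutoff = spec.r2_threshold
    if cutoff >= 1.0:
        cutoff = 1.0 - _PERFECT_LD_TOL

    assigned = np.zeros(len(df), dtype=bool)
    index_variants, removed = [], {}
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        index_variants.append(ids[i])
        cand = np.where(
            ~assigned
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= spec.window_bp)
        )[0]
        if not cand.size:
            continue
        cols = np.array([gidx[v] for v in ids[cand]])
        r2 = _r2_with_index(geno.dosages, gidx[ids[i]], cols)
        hit = cand[r2 >= cutoff]
        for h in hit:
            assigned[h] = True
            removed[ids[h]] = ids[i]
    return ClumpResult(index_variants=index_variants, removed=removed, spec=spec)


def prune(
    geno: GenotypeMatrix,
    r2_threshold: float = 0.2,
    window_bp: int = 500_000,
    step: int = 50,
) -> list:
    """Sliding-window LD pruning; returns surviving variant ids.

    Within each window (ordered by chrom, pos), while any retained pair
    has r2 >= threshold, the member with the smaller MAF is dropped
    (position, then id, breaks ties); the window then slides forward by
    ``step`` variants.  Defaults (500 kb, step 50, r2 0.2) are the
    common choice for preparing a PCA input.
    """
    var = geno.variants
    order = var.sort_values(["chrom", "pos", "id"], kind="mergesort").index.to_numpy()
    freq = geno.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    dropped = np.zeros(len(var), dtype=bool)
    chrom = var["chrom"].to_numpy()
    pos = var["pos"].to_numpy(int)

    start = 0
    while start < len(order):
        i0 = order[start]
        in_win = [
            j
            for j in order[start:]
            if chrom[j] == chrom[i0] and pos[j] - pos[i0] <= window_bp
        ]
        changed = True
        while changed:
            changed = False
            live = [j for j in in_win if not dropped[j]]
            for a in range(len(live)):
                for b in range(a + 1, len(live)):
                    ja, jb = live[a], live[b]
                    if ld_r2(geno.dosages[:, ja], geno.dosages[:, jb]) >= r2_threshold:
                        # drop smaller MAF; ties by later position, then id
                        pair = sorted(
                            (ja, jb),
                            key=lambda j: (maf[j], -pos[j], var.at[j, "id"]),
                        )
                        dropped[pair[0]] = True
                        changed = True
                        break
                if changed:
                    break
        start += step
    return [var.at[j, "id"] for j in order if not dropped[j]]
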