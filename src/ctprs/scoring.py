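"""Clumping-and-thresholding polygenic scores over the (r2, p) grid.

A score is the weighted sum of effect-allele dosages over the clump
index variants passing a p-value threshold, with missing dosages mean-
imputed from the target allele frequency.  The full grid crosses six
clumping r-squared thresholds with five p-value thresholds (30 cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix, SummaryStats
from .ld import ClumpResult

log = logging.getLogger(__name__)

__all__ = ["P_GRID", "PRSGrid", "score", "score_grid", "standardize"]

#: p-value significance thresholds of the grid
P_GRID = (5e-1, 5e-2, 5e-4, 5e-6, 5e-8)


@dataclass
class PRSGrid:
    """Per-sample raw scores for every (r2_threshold, p_threshold) cell."""

    sample_ids: np.ndarray
    scores: dict = field(default_factory=dict)      # (r2, p) -> ndarray
    n_variants: dict = field(default_factory=dict)  # (r2, p) -> int
    empty_cells: set = field(default_factory=set)
    standardization: dict = field(default_factory=dict)  # (r2, p) -> (mean, sd)

    @property
    def cells(self) -> list:
        return sorted(self.scores.keys())

    def nonempty_cells(self) -> list:
        return [c for c in self.cells if c not in self.empty_cells]


def score(
    geno: GenotypeMatrix,
    ss: SummaryStats,
    keep,
    p_threshold: float,
) -> np.ndarray:
    """Weighted sum of effect-allele dosages for one grid cell.

    ``keep`` restricts to the clump index variants; of those, only
    variants with ``p <= p_threshold`` contribute ``beta * dosage``.
    Missing dosages are imputed as twice the effect-allele frequency
    among non-missing target samples.  If nothing passes the threshold,
    an all-zero vector is returned and a warning logged.
    """
    df = ss.table
    keep = set(keep)
    sel = df.index[(df["id"].isin(keep)) & (df["p"] <= p_threshold)]
    if not len(sel):
        log.warning("score: no variants pass p <= %g; returning zeros", p_threshold)
        return np.zeros(geno.n_samples)
    gidx = {vid: j for j, vid in enumerate(geno.variants["id"])}
    cols = np.array([gidx[v] for v in df.loc[sel, "id"]])
    betas = df.loc[sel, "beta"].to_numpy(float)
    dos = geno.dosages[:, cols]
    if np.isnan(dos).any():
        fill = np.nanmean(dos, axis=0)  # equals 2 * effect-allele frequency
        dos = np.where(np.isnan(dos), fill, dos)
    return dos @ betas


def _n_passing(ss: SummaryStats, keep, p_threshold: float) -> int:
    df = ss.table
    return int(((df["id"].isin(set(keep))) & (df["p"] <= p_threshold)).sum())


def score_grid(
    geno: GenotypeMatrix,
    ss: SummaryStats,
    clump_results_by_r2: dict,
) -> PRSGrid:
    """Populate every (r2, p) cell from per-r2 clump results.

    ``clump_results_by_r2`` maps each r2 grid value to its
    :class:`~ctprs.ld.ClumpResult`.  Cells where no variant passes the
    p threshold are flagged empty (they are excluded from tuning, not
    an error: genome-wide-significant cells can legitimately be empty
    at small discovery sizes).
    """
    grid = PRSGrid(sample_ids=geno.sample_ids)
    for r2 in sorted(clump_results_by_r2):
        res: ClumpResult = clump_results_by_r2[r2]
        for p_thr in P_GRID:
            cell = (r2, p_thr)
            n = _n_passing(ss, res.index_variants, p_thr)
            grid.n_variants[cell] = n
            if n == 0:
                grid.empty_cells.add(cell)
                grid.scores[cell] = np.zeros(geno.n_samples)
            else:
                grid.scores[cell] = score(geno, ss, res.index_variants, p_thr)
    return grid


def standardize(scores, params: tuple | None = None):
    """Z-score a score vector; returns ``(standardized, (mean, sd))``.

    With ``params`` given, applies the stored affine transform instead
    (for held-out samples scored with training-fold parameters).  The
    sd uses the n-1 denominator; a zero sd is an error.
    """
    scores = np.asarray(scores, dtype=float)
    if params is None:
        mean = scores.mean()
        sd = scores.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError("standardize: degenerate score (sd = 0)")
        params = (float(mean), float(sd))
    mean, sd = params
    return (scores - mean) / sd, params
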