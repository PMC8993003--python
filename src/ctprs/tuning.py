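"""Grid-cell selection: external-sample tuning and two-fold cross-validation.

Two schemes mirror how C+T hyperparameters (clumping r-squared and
p-value threshold) are tuned in practice.  ``external``: evaluate every
cell on a separate tuning cohort and carry the winning recipe to the
validation cohort.  ``cv2``: split the single cohort into two outcome-
stratified folds, tune within each fold, and score each sample from the
cell chosen without it (out-of-fold assembly, in-fold standardization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import PhenoTable
from .glm import fit_logistic
from .metrics import auc as _auc
from .metrics import pseudo_r2
from .scoring import PRSGrid, standardize

__all__ = ["TuneResult", "tune_external", "tune_cv2"]


@dataclass
class TuneResult:
    scheme: str                         # "external" | "cv2"
    criterion: str
    selected: object                    # cell or per-fold dict of cells
    final_scores: np.ndarray            # per-sample score for association
    cell_criteria: dict = field(default_factory=dict)
    fold_assignment: np.ndarray | None = None
    seed: int | None = None


def _criterion_value(scores, pheno: PhenoTable, criterion: str) -> float:
    """Score one grid cell on one cohort."""
    y = pheno.table["outcome"].to_numpy(float)
    if criterion == "auc":
        X = np.column_stack([np.ones(len(y)), scores])
        fit = fit_logistic(X, y, ["const", "score"])
        return _auc(fit.fitted, y)
    if criterion == "delta_r2":
        from .association import _design

        Xc, nc = _design(pheno, None, include_sex=True, interaction=False)
        Xf = np.column_stack([Xc, np.asarray(scores, float)])
        full = fit_logistic(Xf, y, nc + ["score"])
        cov = fit_logistic(Xc, y, nc)
        null = fit_logistic(np.ones((len(y), 1)), y, ["const"])
        return pseudo_r2(full.loglik, null.loglik, len(y)) - pseudo_r2(
            cov.loglik, null.loglik, len(y)
        )
    raise ValueError(f"unknown tuning criterion {criterion!r}")


def _select(grid: PRSGrid, pheno: PhenoTable, criterion: str, rows=None):
    """Best non-empty cell; ties broken toward (larger p, larger r2)."""
    cells = grid.nonempty_cells()
    if not cells:
        raise ValueError("all grid cells are empty; nothing to tune")
    values = {}
    best, best_key = None, None
    for cell in cells:
        sc = grid.scores[cell] if rows is None else grid.scores[cell][rows]
        ph = pheno if rows is None else PhenoTable(
            pheno.table.iloc[rows].reset_index(drop=True)
        )
        if np.std(sc) == 0:
            continue
        val = _criterion_value(sc, ph, criterion)
        values[cell] = val
        key = (val, cell[1], cell[0])  # criterion, then larger p, larger r2
        if best_key is None or key > best_key:
            best, best_key = cell, key
    if best is None:
        raise ValueError("no grid cell with non-degenerate scores")
    return best, values


def tune_external(
    grid: PRSGrid,
    tune_pheno: PhenoTable,
    criterion: str = "auc",
    validation_grid: PRSGrid | None = None,
) -> TuneResult:
    """Pick the best (r2, p) cell on a tuning cohort.

    ``grid`` must be computed on the tuning cohort; when
    ``validation_grid`` (same recipe applied to the validation cohort)
    is given, the final scores are the selected cell's standardized
    validation scores, otherwise the tuning cohort's own.
    """
    best, values = _select(grid, tune_pheno, criterion)
    source = validation_grid if validation_grid is not None else grid
    final, _ = standardize(source.scores[best])
    return TuneResult(
        scheme="external",
        criterion=criterion,
        selected=best,
        final_scores=final,
        cell_criteria=values,
    )


def tune_cv2(
    grid: PRSGrid,
    pheno: PhenoTable,
    criterion: str = "auc",
    seed: int = 0,
    fold: np.ndarray | None = None,
) -> TuneResult:
    """Two-fold cross-validated tuning on a single cohort.

    Samples are split into two outcome-stratified halves; within each
    fold the best cell is selected, and the samples of the *other* fold
    receive that cell's score, standardized with the tuning fold's mean
    and sd.  Every sample's final score therefore comes from a cell
    chosen without it.
    """
    y = pheno.table["outcome"].to_numpy(int)
    n = len(y)
    if n < 20:
        raise ValueError("tune_cv2 needs n >= 20")
    if fold is None:
        rng = np.random.default_rng(seed)
        fold = np.zeros(n, dtype=int)
        for cls in (0, 1):
            idx = np.where(y == cls)[0]
            rng.shuffle(idx)
            fold[idx[: len(idx) // 2]] = 1
    else:
        fold = np.asarray(fold, dtype=int)
        if fold.shape != (n,) or not set(np.unique(fold)) <= {0, 1}:
            raise ValueError("fold must be a 0/1 vector of length n")
    for f in (0, 1):
        if len(np.unique(y[fold == f])) < 2:
            raise ValueError(
                "a fold has a single outcome class; use a different seed or larger n"
            )

    final = np.empty(n)
    selected = {}
    criteria = {}
    for f in (0, 1):
        tune_rows = np.where(fold == f)[0]
        test_rows = np.where(fold != f)[0]
        best, values = _select(grid, pheno, criterion, rows=tune_rows)
        selected[f] = best
        criteria[f] = values
        _, params = standardize(grid.scores[best][tune_rows])
        final[test_rows], _ = standardize(grid.scores[best][test_rows], params)
    return TuneResult(
        scheme="cv2",
        criterion=criterion,
        selected=selected,
        final_scores=final,
        cell_criteria=criteria,
        fold_assignment=fold,
        seed=seed,
    )
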