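"""Logistic association of a polygenic score with a binary outcome.

This is the reporting stage: adjusted odds ratios with Wald confidence
intervals, discrimination (AUC, S80), the Nagelkerke pseudo-R-squared
increment over the covariate-only model, and Hosmer-Lemeshow
calibration.  The entry point is the statsmodels-style pair
:class:`PRSAssociation` (model, built from a standardized score vector
and a phenotype table) whose :meth:`~PRSAssociation.fit` returns an
:class:`AssociationResults` carrying the coefficient table and metric
suite, with a :meth:`~AssociationResults.summary` table formatted the
way PRS association studies report them (aOR (95% CI), p, AUC, S80,
delta R-squared in percentage points).

Covariate sets follow the study design this pipeline emulates: sex,
intervention status, cohort (dummy-coded against the first level) and
the first ten ancestry principal components; interaction models add a
sex-by-score term, and sex-stratified models drop the sex covariate
within each stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PhenoTable
from .glm import LogitFit, fit_logistic
from .metrics import auc, hosmer_lemeshow, pseudo_r2, s80

__all__ = [
    "PRSAssociation",
    "AssociationResults",
    "assoc_prs",
    "interaction_model",
    "stratified_models",
]

_Z975 = 1.959964  # two-sided 95% Wald quantile


def _design(
    pheno: PhenoTable,
    scores: np.ndarray | None,
    include_sex: bool = True,
    interaction: bool = False,
):
    """Build (X, names) with intercept, PRS, covariates, optional sex x PRS."""
    df = pheno.table
    cols = [np.ones(len(df))]
    names = ["const"]
    if scores is not None:
        cols.append(np.asarray(scores, dtype=float))
        names.append("PRS")
    if include_sex:
        cols.append(df["sex"].to_numpy(float))
        names.append("sex")
    cols.append(df["intervention"].to_numpy(float))
    names.append("intervention")
    levels = sorted(pd.unique(df["cohort"].astype(str)))
    for lev in levels[1:]:
        cols.append((df["cohort"].astype(str) == lev).to_numpy(float))
        names.append(f"cohort[{lev}]")
    for pc in pheno.pc_columns:
        cols.append(df[pc].to_numpy(float))
        names.append(pc)
    if interaction:
        if scores is None or not include_sex:
            raise ValueError("interaction model needs both PRS and sex terms")
        cols.append(np.asarray(scores, float) * df["sex"].to_numpy(float))
        names.append("sex:PRS")
    return np.column_stack(cols), names


@dataclass
class AssociationResults:
    """One fitted model's coefficient table and evaluation metrics."""

    label: str
    coef_table: pd.DataFrame      # term, estimate, se, z, p, aOR, ci_low, ci_high
    auc: float
    s80: float
    delta_r2: float               # percentage points over covariate-only model
    hl_stat: float
    hl_p: float
    n: int
    n_cases: int
    converged: bool
    fit: LogitFit = field(repr=False, default=None)
    covariate_fit: LogitFit = field(repr=False, default=None)
    headline_term: str = "PRS"

    @property
    def headline(self) -> pd.Series:
        """The row of the coefficient of interest (PRS or sex:PRS)."""
        return self.coef_table.set_index("term").loc[self.headline_term]

    def summary(self) -> str:
        h = self.headline
        lines = [
            f"Model: {self.label}   n={self.n}  cases={self.n_cases}"
            + ("" if self.converged else "  [NOT CONVERGED]"),
            "",
            self.coef_table.to_string(
                index=False,
                formatters={
                    "estimate": "{:+.4f}".format,
                    "se": "{:.4f}".format,
                    "z": "{:+.3f}".format,
                    "p": "{:.4g}".format,
                    "aOR": "{:.3f}".format,
                    "ci_low": "{:.3f}".format,
                    "ci_high": "{:.3f}".format,
                },
            ),
            "",
            f"{self.headline_term}: aOR = {h['aOR']:.2f} "
            f"(95% CI: {h['ci_low']:.2f}, {h['ci_high']:.2f}), p = {h['p']:.3g}",
            f"AUC = {self.auc:.2f}   S80 = {self.s80:.2f}   "
            f"delta R2 = {self.delta_r2:.1f}%",
            f"Hosmer-Lemeshow: chi2 = {self.hl_stat:.2f}, p = {self.hl_p:.3f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "coefficients": self.coef_table.to_dict(orient="records"),
            "auc": self.auc,
            "s80": self.s80,
            "delta_r2": self.delta_r2,
            "hl_stat": self.hl_stat,
            "hl_p": self.hl_p,
            "n": self.n,
            "n_cases": self.n_cases,
            "converged": self.converged,
        }


class PRSAssociation:
    """Logistic association model of a standardized PRS with the outcome.

    Parameters
    ----------
    scores
        Per-sample polygenic score, aligned to ``pheno`` row order;
        conventionally standardized so the aOR is per 1 SD.
    pheno
        :class:`~ctprs.containers.PhenoTable` with outcome, sex,
        intervention, cohort and any ``PC*`` columns (all PCs present
        are used as covariates).
    kind
        ``"main"`` (default) or ``"interaction"`` (adds sex x PRS, the
        interaction row becomes the headline coefficient).
    """

    def __init__(self, scores, pheno: PhenoTable, kind: str = "main"):
        if kind not in ("main", "interaction"):
            raise ValueError("kind must be 'main' or 'interaction'")
        self.scores = np.asarray(scores, dtype=float)
        if len(self.scores) != len(pheno):
            raise ValueError("scores and phenotype table length mismatch")
        self.pheno = pheno
        self.kind = kind

    def fit(self, hl_groups: int = 10) -> AssociationResults:
        return _fit_assoc(
            self.scores,
            self.pheno,
            label=self.kind,
            include_sex=True,
            interaction=self.kind == "interaction",
            hl_groups=hl_groups,
        )

    def fit_stratified(self, hl_groups: int = 10) -> dict:
        """Fit per-sex models (sex covariate dropped); see :func:`stratified_models`."""
        return stratified_models(self.scores, self.pheno, hl_groups=hl_groups)


def _fit_assoc(
    scores,
    pheno: PhenoTable,
    label: str,
    include_sex: bool = True,
    interaction: bool = False,
    hl_groups: int = 10,
) -> AssociationResults:
    y = pheno.table["outcome"].to_numpy(float)
    X_full, names_full = _design(pheno, scores, include_sex, interaction)
    if interaction:
        # reference for the increment is the main-effects model (covariates + PRS)
        X_cov, names_cov = _design(pheno, scores, include_sex, False)
    else:
        X_cov, names_cov = _design(pheno, None, include_sex, False)

    full = fit_logistic(X_full, y, names_full)
    cov = fit_logistic(X_cov, y, names_cov)

    z, p = full.wald()
    est = full.params
    se = full.bse
    table = pd.DataFrame(
        {
            "term": names_full,
            "estimate": est,
            "se": se,
            "z": z,
            "p": p,
            "aOR": np.exp(est),
            "ci_low": np.exp(est - _Z975 * se),
            "ci_high": np.exp(est + _Z975 * se),
        }
    )

    n = len(y)
    # null (intercept-only) reference for the Nagelkerke values
    X0 = np.ones((n, 1))
    null = fit_logistic(X0, y, ["const"])
    r2_full = pseudo_r2(full.loglik, null.loglik, n)
    r2_cov = pseudo_r2(cov.loglik, null.loglik, n)
    hl_stat, hl_p = hosmer_lemeshow(full.fitted, y, g=hl_groups)

    return AssociationResults(
        label=label,
        coef_table=table,
        auc=auc(full.fitted, y),
        s80=s80(full.fitted, y),
        delta_r2=100.0 * (r2_full - r2_cov),
        hl_stat=hl_stat,
        hl_p=hl_p,
        n=n,
        n_cases=int(y.sum()),
        converged=full.converged,
        fit=full,
        covariate_fit=cov,
        headline_term="sex:PRS" if interaction else "PRS",
    )


def assoc_prs(scores, pheno: PhenoTable, hl_groups: int = 10) -> AssociationResults:
    """Main-effect model: outcome ~ PRS + sex + intervention + cohort + PCs."""
    return PRSAssociation(scores, pheno, kind="main").fit(hl_groups=hl_groups)


def interaction_model(scores, pheno: PhenoTable, hl_groups: int = 10) -> AssociationResults:
    """Adds a sex x PRS term; the interaction row is the headline coefficient."""
    return PRSAssociation(scores, pheno, kind="interaction").fit(hl_groups=hl_groups)


def stratified_models(scores, pheno: PhenoTable, hl_groups: int = 10) -> dict:
    """Per-sex fits with the sex covariate dropped.

    Returns ``{"female": AssociationResults | None, "male": ...}``;
    a stratum whose outcome is single-class is skipped with a warning
    (mapped to None).
    """
    import logging

    out = {}
    scores = np.asarray(scores, dtype=float)
    for code, label in ((0, "female"), (1, "male")):
        mask = pheno.table["sex"].to_numpy() == code
        sub = PhenoTable(pheno.table.loc[mask].reset_index(drop=True))
        ysub = sub.table["outcome"]
        if ysub.nunique() < 2:
            logging.getLogger(__name__).warning(
                "stratified_models: %s stratum has a single outcome class; skipped",
                label,
            )
            out[label] = None
            continue
        out[label] = _fit_assoc(
            scores[mask], sub, label=f"stratified[{label}]",
            include_sex=False, hl_groups=hl_groups,
        )
    return out
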