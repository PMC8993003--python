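"""Detectable odds ratio for a standardized predictor in logistic regression.

The closed form is the normal-approximation sample-size formula for a
1-SD continuous predictor solved for the effect size: with case
fraction ``p = n_cases / n``,

    log OR = (z_{1-alpha/2} + z_{power}) / sqrt(n * p * (1 - p))

A Monte-Carlo simulation of the actual Wald test cross-validates the
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .glm import SeparationError, fit_logistic

__all__ = [
    "PowerSpec",
    "PowerResult",
    "detectable_or_closed_form",
    "power_by_simulation",
]


@dataclass
class PowerSpec:
    n: int
    n_cases: int
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.n_cases < self.n:
            raise ValueError("need 0 < n_cases < n")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


@dataclass
class PowerResult:
    detectable_or: float
    method: str
    reps: int | None = None
    mc_se: float | None = None


def detectable_or_closed_form(spec: PowerSpec) -> PowerResult:
    """Minimal detectable OR per 1 SD of predictor (closed form)."""
    p = spec.n_cases / spec.n
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    log_or = (z_a + z_b) / np.sqrt(spec.n * p * (1 - p))
    return PowerResult(detectable_or=float(np.exp(log_or)), method="closed_form")


def _intercept_for_prevalence(beta: float, prevalence: float) -> float:
    """Solve E[expit(a + beta X)] = prevalence for standard-normal X."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(101)
    weights = weights / weights.sum()

    def expected(a):
        return float(weights @ (1.0 / (1.0 + np.exp(-(a + beta * nodes))))) - prevalence

    return optimize.brentq(expected, -30, 30, xtol=1e-10)


def power_by_simulation(
    spec: PowerSpec, or_value: float, reps: int = 2000, seed: int = 0
) -> dict:
    """Monte-Carlo power of the Wald test at the given odds ratio.

    Each replicate draws a standard-normal predictor for ``n`` samples,
    generates outcomes from a logistic model whose intercept is solved
    so the expected case count equals ``n_cases``, fits the logistic
    regression and tests the slope at ``alpha``.  Returns the rejection
    fraction with its Monte-Carlo standard error.
    """
    if reps < 500:
        raise ValueError("reps must be >= 500")
    beta = np.log(or_value)
    a = _intercept_for_prevalence(beta, spec.n_cases / spec.n)
    rng = np.random.default_rng(seed)
    rejected = 0
    excluded = 0
    for _ in range(reps):
        x = rng.standard_normal(spec.n)
        pr = 1.0 / (1.0 + np.exp(-(a + beta * x)))
        y = (rng.uniform(size=spec.n) < pr).astype(float)
        if y.sum() in (0, spec.n):
            excluded += 1
            continue
        X = np.column_stack([np.ones(spec.n), x])
        try:
            fit = fit_logistic(X, y, ["const", "x"])
        except SeparationError:
            excluded += 1
            continue
        _, p = fit.wald()
        if p[1] < spec.alpha:
            rejected += 1
    used = reps - excluded
    if excluded > 0.05 * reps:
        import logging

        logging.getLogger(__name__).warning(
            "power_by_simulation: %d/%d replicates excluded", excluded, reps
        )
    power = rejected / used
    return {
        "power": power,
        "mc_se": float(np.sqrt(power * (1 - power) / used)),
        "reps_used": used,
        "excluded": excluded,
    }
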