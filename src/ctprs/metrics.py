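"""Discrimination and calibration metrics for binary-outcome models."""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["auc", "s80", "pseudo_r2", "hosmer_lemeshow"]


def _check_two_classes(y):
    y = np.asarray(y)
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("both outcome classes must be present")
    return y


def auc(fitted_probs, y) -> float:
    """Probability a random case outranks a random control (ties 1/2).

    The Mann-Whitney form of the area under the ROC curve: 0.5 means no
    separation, 1 perfect separation.
    """
    y = _check_two_classes(y)
    s = np.asarray(fitted_probs, dtype=float)
    ranks = stats.rankdata(s)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def s80(fitted_probs, y, specificity: float = 0.80, interpolate: bool = False) -> float:
    """Sensitivity at the most liberal threshold with specificity >= 0.80.

    Thresholds classify ``prob >= t`` as positive.  Scanning thresholds
    from strict to liberal, sensitivity rises as specificity falls; the
    last threshold still meeting the specificity floor defines S80.
    ``interpolate=True`` instead linearly interpolates sensitivity
    between the two thresholds straddling the exact specificity.
    """
    y = _check_two_classes(y)
    s = np.asarray(fitted_probs, dtype=float)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    # candidate thresholds: +inf (nothing positive) then unique scores desc
    cand = np.concatenate(([np.inf], np.unique(s)[::-1]))
    best_sens, prev = 0.0, (1.0, 0.0)
    for t in cand:
        pos = s >= t
        sens = float((pos & (y == 1)).sum() / n1)
        spec = float((~pos & (y == 0)).sum() / n0)
        if spec >= specificity:
            best_sens, prev = sens, (spec, sens)
        else:
            if interpolate and prev[0] > spec:
                frac = (prev[0] - specificity) / (prev[0] - spec)
                return float(prev[1] + frac * (sens - prev[1]))
            break
    return best_sens


def pseudo_r2(loglik_full: float, loglik_null: float, n: int, kind: str = "nagelkerke") -> float:
    """Likelihood-based pseudo R-squared of a fitted binary model.

    ``nagelkerke`` (default) rescales Cox-Snell by its attainable
    maximum; ``cox-snell`` and ``mcfadden`` are available behind the
    flag.  ``loglik_null`` is the intercept-only (or covariate-only,
    for increments) log-likelihood.
    """
    if n == 0:
        raise ValueError("n must be positive")
    if kind == "mcfadden":
        return float(1 - loglik_full / loglik_null)
    cs = 1 - np.exp(2 * (loglik_null - loglik_full) / n)
    if kind == "cox-snell":
        return float(cs)
    if kind == "nagelkerke":
        denom = 1 - np.exp(2 * loglik_null / n)
        return float(cs / denom) if denom > 0 else 0.0
    raise ValueError(f"unknown pseudo-R2 kind {kind!r}")


def hosmer_lemeshow(fitted_probs, y, g: int = 10):
    """Hosmer-Lemeshow calibration test over ``g`` risk groups.

    Samples are sorted by fitted probability and cut into ``g``
    near-equal groups with tied probabilities kept together; the
    statistic sums ``(O - E)^2 / (E (1 - E/n_g))`` over groups and is
    referred to chi-square with ``g - 2`` degrees of freedom.  Groups
    with degenerate expectation are merged with a neighbour (degrees of
    freedom reduced, warning logged).
    """
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(p)
    if n < 2 * g:
        raise ValueError(f"need n >= 2g (n={n}, g={g})")
    order = np.argsort(p, kind="mergesort")
    p_s, y_s = p[order], y[order]

    # near-equal group boundaries; shift boundaries so ties stay together
    edges = [int(round(n * k / g)) for k in range(1, g)]
    bounds = []
    for e in edges:
        while 0 < e < n and p_s[e] == p_s[e - 1]:
            e += 1
        bounds.append(min(e, n))
    bounds = sorted(set(b for b in bounds if 0 < b < n)) + [n]

    groups = []
    start = 0
    for b in bounds:
        if b > start:
            groups.append((start, b))
            start = b

    O = np.array([y_s[a:b].sum() for a, b in groups])
    E = np.array([p_s[a:b].sum() for a, b in groups])
    ng = np.array([b - a for a, b in groups], dtype=float)

    # merge groups whose expected counts are degenerate
    merged = 0
    k = 0
    O, E, ng = list(O), list(E), list(ng)
    while k < len(O):
        if E[k] <= 0 or E[k] >= ng[k]:
            j = k - 1 if k > 0 else k + 1
            if j < 0 or j >= len(O):
                break
            O[j] += O.pop(k)
            E[j] += E.pop(k)
            ng[j] += ng.pop(k)
            merged += 1
        else:
            k += 1
    if merged:
        log.warning("hosmer_lemeshow: merged %d degenerate group(s)", merged)
    O, E, ng = np.array(O), np.array(E), np.array(ng)

    stat = float(np.sum((O - E) ** 2 / (E * (1 - E / ng))))
    df = len(O) - 2
    if df < 1:
        return stat, 1.0
    return stat, float(stats.chi2.sf(stat, df))
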