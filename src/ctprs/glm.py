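"""Logistic regression by IRLS with explicit failure semantics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LogitFit", "fit_logistic", "SeparationError", "RankDeficiencyError"]


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: coefficients diverge."""


class RankDeficiencyError(RuntimeError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass
class LogitFit:
    params: np.ndarray
    cov: np.ndarray          # observed-information covariance
    loglik: float
    fitted: np.ndarray       # fitted probabilities
    n_iter: int
    converged: bool
    names: list

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald(self):
        """(z, p) per coefficient, two-sided normal reference."""
        from scipy import stats

        z = self.params / self.bse
        return z, 2 * stats.norm.sf(np.abs(z))


def _check_rank(X: np.ndarray, names) -> None:
    # pivoted QR flags columns with negligible diagonal contribution
    _, R, piv = _qr_pivot(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[piv[k]] for k in range(rank, X.shape[1])]
        raise RankDeficiencyError(f"collinear design column(s): {bad}")


def _qr_pivot(X):
    from scipy.linalg import qr

    return qr(X, mode="economic", pivoting=True)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogitFit:
    """Fit P(y=1) = expit(X beta) by iteratively reweighted least squares.

    ``X`` must already contain the intercept column.  Convergence is a
    relative log-likelihood change below ``tol`` (default 1e-10, max 100
    iterations); the covariance is the inverse observed information.
    Raises :class:`RankDeficiencyError` for collinear designs and
    :class:`SeparationError` when fitted probabilities pin to 0/1 with
    diverging coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if n <= k:
        raise ValueError(f"need n > number of terms ({n} <= {k})")
    _check_rank(X, names)

    beta = np.zeros(k)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        eta = np.clip(eta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        ll = float(np.sum(y * np.log(mu + 1e-320) + (1 - y) * np.log(1 - mu + 1e-320)))

        # separation: essentially perfect classification with huge coefficients
        pinned = np.all((mu < 1e-8) | (mu > 1 - 1e-8))
        if (pinned and np.abs(beta).max() > 20) or np.abs(beta).max() > 1e3:
            raise SeparationError(
                "perfect separation detected: fitted probabilities reached 0/1 "
                "with diverging coefficients"
            )

        if ll_old > -np.inf and abs(ll - ll_old) <= tol * (abs(ll_old) + tol):
            XtWX = (X * w[:, None]).T @ X
            cov = np.linalg.inv(XtWX)
            return LogitFit(beta, cov, ll, mu, it, True, list(names))
        ll_old = ll

        wz = np.clip(w, 1e-10, None)
        z = eta + (y - mu) / wz
        XtWX = (X * wz[:, None]).T @ X
        try:
            beta = np.linalg.solve(XtWX, (X * wz[:, None]).T @ z)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise RankDeficiencyError(str(exc)) from exc

    # ran out of iterations: report non-convergence honestly
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    ll = float(np.sum(y * np.log(mu + 1e-320) + (1 - y) * np.log(1 - mu + 1e-320)))
    return LogitFit(beta, cov, ll, mu, max_iter, False, list(names))
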