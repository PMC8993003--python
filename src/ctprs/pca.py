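"""Genotype PCA for population-stratification covariates.

Dosages are mean-imputed, centered by twice the allele frequency and
scaled by ``sqrt(2 f (1 - f))`` — the standard genotype standardization
— before a truncated eigendecomposition of the sample covariance.  A
deterministic sign convention (the largest-magnitude loading of each
component is positive) makes results reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix

__all__ = ["PCResult", "compute_pcs"]


@dataclass
class PCResult:
    coords: np.ndarray            # n x k sample coordinates
    explained_var: np.ndarray     # fraction per component, non-increasing
    loadings: np.ndarray          # m x k variant loadings
    freqs: np.ndarray             # standardization frequencies
    sample_ids: np.ndarray
    variant_ids: np.ndarray

    def pc_frame(self):
        import pandas as pd

        k = self.coords.shape[1]
        df = pd.DataFrame(self.coords, columns=[f"PC{i + 1}" for i in range(k)])
        df.insert(0, "IID", self.sample_ids)
        return df


def compute_pcs(geno: GenotypeMatrix, pruned=None, k: int = 10) -> PCResult:
    """First ``k`` principal components of the (pruned) genotype matrix.

    ``pruned`` is the variant-id list from LD pruning (all variants if
    None).  ``k`` must satisfy ``k <= min(n - 1, m)``.
    """
    if pruned is not None:
        keep = set(pruned)
        if not keep:
            raise ValueError("pruned variant set is empty")
        cols = np.where(geno.variants["id"].isin(keep))[0]
        geno = geno.subset_variants(cols)
    n, m = geno.dosages.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} too large for n={n}, m={m}")

    f = geno.allele_freq()
    X = geno.dosages
    # mean-impute, then standardize by 2f and sqrt(2f(1-f))
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X = np.where(nan_mask, np.broadcast_to(2 * f, X.shape), X)
    sd = np.sqrt(2 * f * (1 - f))
    sd[sd == 0] = 1.0
    Z = (X - 2 * f) / sd

    # eigendecomposition of the smaller Gram matrix (n x n or m x m)
    if m <= n:
        G = Z.T @ Z
        w, V = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        w, V = np.maximum(w[order], 0.0), V[:, order]
        S = np.sqrt(w)
        loadings = V[:, :k]
        with np.errstate(invalid="ignore", divide="ignore"):
            coords = Z @ loadings
    else:
        G = Z @ Z.T
        w, U = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        w, U = np.maximum(w[order], 0.0), U[:, order]
        S = np.sqrt(w)
        coords = U[:, :k] * S[:k]
        with np.errstate(invalid="ignore", divide="ignore"):
            loadings = Z.T @ (U[:, :k] / np.where(S[:k] > 0, S[:k], 1.0))
    var = w
    explained = var / var.sum() if var.sum() > 0 else var

    # sign convention: largest-|loading| entry positive per component
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            coords[:, c] *= -1

    return PCResult(
        coords=coords,
        explained_var=explained[:k],
        loadings=loadings,
        freqs=f,
        sample_ids=geno.sample_ids,
        variant_ids=geno.variants["id"].to_numpy(),
    )
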