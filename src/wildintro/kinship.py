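"""Genomic relationship matrices (VanRaden method 1, optionally SNP-weighted)."""

from __future__ import annotations

import numpy as np

from .containers import GenotypeMatrix, KinshipMatrix


def make_grm(g: GenotypeMatrix, weights=None, method_tag: str = "") -> KinshipMatrix:
    """VanRaden method-1 GRM from a dosage matrix.

    Dosages are centered by twice the observed counted-allele frequency
    per site; missing dosages are mean-imputed (i.e. contribute zero after
    centering). With per-site nonnegative weights ``w``,

        K = W diag(w) W' / (2 * sum_j w_j p_j (1 - p_j))

    so uniform weights reproduce the unweighted GRM and rescaling all
    weights by a constant leaves K unchanged. Monomorphic sites are
    dropped before computation.
    """
    X = g.dosage.astype(float).copy()
    p = np.nanmean(X, axis=0) / 2.0
    with np.errstate(invalid="ignore"):
        var = np.nanvar(X, axis=0)
    poly = np.isfinite(p) & (var > 0) & (p > 0) & (p < 1)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape[0] != g.n_sites:
            raise ValueError("weights length must equal number of sites")
        if (weights < 0).any():
            raise ValueError("weights must be nonnegative")
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic sites for a GRM")
    X = X[:, poly]
    p = p[poly]
    w = np.ones(poly.sum()) if weights is None else weights[poly]
    W = X - 2 * p[None, :]
    W[~np.isfinite(W)] = 0.0  # mean imputation
    denom = 2.0 * float(np.sum(w * p * (1 - p)))
    K = (W * w[None, :]) @ W.T / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(samples=list(g.samples), K=K, method_tag=method_tag or "vanraden1")


def offdiag_correlation(k1: KinshipMatrix, k2: KinshipMatrix) -> float:
    """Pearson correlation of the strictly-upper-triangle entries of two GRMs."""
    if k1.samples != k2.samples:
        raise ValueError("kinship matrices must cover the same samples in the same order")
    iu = np.triu_indices(len(k1.samples), k=1)
    return float(np.corrcoef(k1.K[iu], k2.K[iu])[0, 1])
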