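"""Distance and linkage-disequilibrium primitives on dosage matrices.

The Hamming distance here is the allele-count mismatch metric on hard
(integer-rounded) dosages: sum_i |a_i - b_i| over sites non-missing in
both vectors. Only distance *rankings* are consumed downstream (panel
selection), so the metric choice matters up to rank stability.
"""

from __future__ import annotations

import numpy as np

from .containers import GenotypeMatrix


def hamming_distance(a, b) -> float:
    """Allele-count mismatch distance between two dosage vectors.

    Fractional dosages are rounded to the nearest integer (ties to even)
    before differencing; sites missing in either vector are skipped.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.abs(np.round(a[ok]) - np.round(b[ok])).sum())


def hamming_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs Hamming distances between rows of A and rows of B.

    Vectorized equivalent of calling :func:`hamming_distance` on every
    (row of A, row of B) pair; rows are hard-rounded, missing skipped
    pairwise.
    """
    Ar = np.round(np.asarray(A, dtype=float))
    Br = np.round(np.asarray(B, dtype=float))
    out = np.empty((Ar.shape[0], Br.shape[0]))
    for j in range(Br.shape[0]):
        diff = np.abs(Ar - Br[j][None, :])
        out[:, j] = np.nansum(diff, axis=1)
    return out


def _corr_columns(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation between every column of X and every column of Y.

    Missing values are handled by pairwise-complete observations only when
    present; monomorphic (zero-variance) columns yield NaN.
    """
    if np.isfinite(X).all() and np.isfinite(Y).all():
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        sx = np.sqrt((Xc**2).sum(axis=0))
        sy = np.sqrt((Yc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ Yc) / np.outer(sx, sy)
        r[~np.isfinite(r)] = np.nan
        return r
    # slow pairwise-complete fallback
    r = np.full((X.shape[1], Y.shape[1]), np.nan)
    for i in range(X.shape[1]):
        xi = X[:, i]
        for j in range(Y.shape[1]):
            yj = Y[:, j]
            ok = np.isfinite(xi) & np.isfinite(yj)
            if ok.sum() < 2:
                continue
            xs, ys = xi[ok], yj[ok]
            if xs.std() == 0 or ys.std() == 0:
                continue
            r[i, j] = np.corrcoef(xs, ys)[0, 1]
    return r


def pairwise_r2(g: GenotypeMatrix, set_a, set_b) -> np.ndarray:
    """Squared Pearson correlation of dosage columns, per (a, b) pair.

    Returns an array of shape (len(set_a), len(set_b)); NaN where either
    column is monomorphic.
    """
    set_a = np.asarray(set_a, dtype=int)
    set_b = np.asarray(set_b, dtype=int)
    if set_a.size == 0 or set_b.size == 0:
        raise ValueError("site index sets must be non-empty")
    r = _corr_columns(g.dosage[:, set_a], g.dosage[:, set_b])
    return r**2


def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 10, r2_max: float = 0.3) -> np.ndarray:
    """Greedy sliding-window LD pruning of sites.

    Within each window of ``window`` sites advanced by ``step``, any pair of
    retained sites with squared dosage correlation > ``r2_max`` has its
    *later* site removed. Monomorphic sites are retained untested
    (correlation undefined). Returns sorted retained site indices.
    """
    m = g.n_sites
    if m < 2:
        raise ValueError("need at least 2 sites")
    keep = np.ones(m, dtype=bool)
    starts = list(range(0, max(m - window, 0) + 1, step))
    if not starts or starts[-1] + window < m:
        starts.append(max(m - window, 0))
    for s in starts:
        idx = np.arange(s, min(s + window, m))
        idx = idx[keep[idx]]
        if idx.size < 2:
            continue
        r2 = _corr_columns(g.dosage[:, idx], g.dosage[:, idx]) ** 2
        alive = np.ones(idx.size, dtype=bool)
        for i in range(idx.size):
            if not alive[i]:
                continue
            for j in range(i + 1, idx.size):
                if alive[j] and np.isfinite(r2[i, j]) and r2[i, j] > r2_max:
                    alive[j] = False
        keep[idx[~alive]] = False
    return np.flatnonzero(keep)
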