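"""Two-stage genomic prediction with deregressed BLUPs and shared-fold CV.

Stage 1 fits an identity-covariance clone model to plot records (the same
fit used as the GWAS response) and yields clone BLUPs with prediction
error variances. The BLUPs are deregressed by their reliability
r2 = 1 - PEV/sigma2_g (dEBV = BLUP / r2) and given error-variance weights

    w = (1 - h2) / ((c + (1 - r2) / r2) * h2)

where c is the fraction of genetic variance unaccounted by markers.
Stage 2 trains kinship mixed models on the dEBVs (per-record residual
variance sigma2_e / w) and predicts held-out clones through their kinship
with the training set; accuracy is the test-set correlation of stage-1
BLUP and GEBV, with identical fold assignments for every model compared.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.model_selection import KFold

from . import reml
from .containers import KinshipMatrix
from .reml import RandomTerm, VarCompFit

log = logging.getLogger(__name__)

MODEL_KERNELS = {
    "ALL": ("all",),
    "PARTITIONED": ("idm", "non_idm"),
    "IDMnull": ("non_idm",),
}


def deregress(stage1: VarCompFit, c: float = 0.5, genetic_label: str = "g_iid") -> pd.DataFrame:
    """Deregress stage-1 clone BLUPs with reliability-based weights.

    Requires a fit carrying BLUPs and PEV for ``genetic_label``. Clones
    with reliability <= 0 are excluded with a warning. Returns a table
    with columns clone, blup, pev, r2, debv, weight.
    """
    s2g = stage1.sigma2.get(genetic_label, 0.0)
    if s2g <= 0:
        raise ValueError("stage-1 genetic variance is zero; nothing to deregress")
    if genetic_label not in stage1.pev:
        raise ValueError("stage-1 fit has no PEV; refit with want_pev=True")
    clones = stage1.details["levels"][genetic_label]
    blup = np.asarray(stage1.blups[genetic_label], dtype=float)
    pev = np.asarray(stage1.pev[genetic_label], dtype=float)
    r2 = 1.0 - pev / s2g
    h2 = s2g / (s2g + stage1.sigma2["residual"])
    ok = r2 > 0
    if (~ok).any():
        log.warning("excluding %d clones with reliability <= 0", int((~ok).sum()))
    r2 = np.clip(r2, None, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        debv = blup / r2
        weight = (1.0 - h2) / ((c + (1.0 - r2) / r2) * h2)
    out = pd.DataFrame(
        {"clone": clones, "blup": blup, "pev": pev, "r2": r2, "debv": debv,
         "weight": weight}
    )[ok]
    out.attrs["h2"] = h2
    out.attrs["c"] = c
    return out.reset_index(drop=True)


def _predict_fold(dereg, train_idx, test_idx, kernels, Ks):
    """Train a (possibly multi-kernel) weighted model; return test GEBVs."""
    ytr = dereg["debv"].to_numpy()[train_idx]
    wtr = dereg["weight"].to_numpy()[train_idx]
    Xtr = np.ones((len(train_idx), 1))
    terms = [
        RandomTerm(k, np.eye(len(train_idx)), Ks[k][np.ix_(train_idx, train_idx)])
        for k in kernels
    ]
    fit = reml.fit(ytr, Xtr, terms, weights=wtr, want_blups=False)
    s2e = fit.sigma2["residual"]
    V = np.diag(s2e / wtr)
    for k in kernels:
        V += fit.sigma2[k] * Ks[k][np.ix_(train_idx, train_idx)]
    cholV = cho_factor(V, lower=True)
    resid = ytr - Xtr @ fit.beta
    alpha = cho_solve(cholV, resid)
    gebv = np.zeros(len(test_idx))
    for k in kernels:
        gebv += fit.sigma2[k] * (Ks[k][np.ix_(test_idx, train_idx)] @ alpha)
    return gebv, fit


def cross_validate(
    dereg: pd.DataFrame,
    kinships: dict[str, KinshipMatrix],
    models=("ALL", "PARTITIONED", "IDMnull"),
    reps: int = 10,
    folds: int = 5,
    seed: int = 0,
    trait: str = "",
    extra_partitions: dict | None = None,
    truth: pd.Series | None = None,
) -> pd.DataFrame:
    """Replicated k-fold cross-validation with fold sharing across models.

    ``extra_partitions`` maps a model label (e.g. ``"RANDOM_1"``) to a
    ``{"idm": K, "non_idm": K}`` pair fitted like PARTITIONED. When
    ``truth`` (true breeding values, synthetic diagnostics only) is given,
    a ``truth_accuracy`` column is added. Fold assignments are drawn once
    per replicate and hashed into ``fold_hash`` so sharing is checkable.
    """
    clones = dereg["clone"].tolist()
    if len(clones) < 2 * folds:
        raise ValueError("need at least 2 clones per fold")
    Ks_by_model = {}
    for m in models:
        keys = MODEL_KERNELS[m]
        Ks_by_model[m] = (keys, {k: kinships[k].align(clones) for k in keys})
    for label, pair in (extra_partitions or {}).items():
        keys = ("idm", "non_idm")
        Ks_by_model[label] = (keys, {k: pair[k].align(clones) for k in keys})

    rows = []
    for rep in range(1, reps + 1):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        assignment = list(kf.split(np.arange(len(clones))))
        digest = hashlib.sha1(
            b"".join(np.sort(te).tobytes() for _, te in assignment)
        ).hexdigest()[:12]
        for fold, (tr, te) in enumerate(assignment, start=1):
            if te.size < 2:
                for m in Ks_by_model:
                    rows.append((trait, m, rep, fold, np.nan, np.nan, digest))
                continue
            ref = dereg["blup"].to_numpy()[te]
            for m, (keys, Ks) in Ks_by_model.items():
                gebv, _ = _predict_fold(dereg, tr, te, keys, Ks)
                # constant GEBV (all genetic variance at zero) -> undefined
                acc = (
                    float(np.corrcoef(ref, gebv)[0, 1])
                    if np.std(gebv) > 0 and np.std(ref) > 0
                    else np.nan
                )
                tacc = np.nan
                if truth is not None:
                    tv = truth.reindex([clones[i] for i in te]).to_numpy(dtype=float)
                    if np.isfinite(tv).all():
                        tacc = float(np.corrcoef(tv, gebv)[0, 1])
                rows.append((trait, m, rep, fold, acc, tacc, digest))
    out = pd.DataFrame(
        rows, columns=["trait", "model", "rep", "fold", "accuracy",
                       "truth_accuracy", "fold_hash"]
    )
    out.attrs["seed"] = seed
    return out


def compare_models(cv: pd.DataFrame, h2_idm: pd.Series | None = None) -> pd.DataFrame:
    """Pairwise accuracy differences per trait, and their relation to the
    introgression heritability.

    Reports mean and standard deviation of PARTITIONED-IDMnull,
    ALL-IDMnull and ALL-PARTITIONED per trait. When ``h2_idm`` (per-trait
    introgression heritability) is given, the correlation across traits of
    each mean difference with h2_idm lands in
    ``.attrs['cor_with_h2_idm']``.
    """
    pairs = [("PARTITIONED", "IDMnull"), ("ALL", "IDMnull"), ("ALL", "PARTITIONED")]
    piv = cv.pivot_table(index=["trait", "rep", "fold"], columns="model",
                         values="accuracy")
    rows = []
    for trait, grp in piv.groupby(level="trait"):
        for a, b in pairs:
            if a in grp.columns and b in grp.columns:
                d = (grp[a] - grp[b]).dropna()
                rows.append((trait, f"{a}-{b}", d.mean(), d.std(), len(d)))
    out = pd.DataFrame(rows, columns=["trait", "contrast", "mean_diff", "sd_diff", "n"])
    if h2_idm is not None:
        cors = {}
        for contrast, grp in out.groupby("contrast"):
            joined = grp.set_index("trait")["mean_diff"].align(h2_idm, join="inner")
            if len(joined[0]) >= 3:
                cors[contrast] = float(np.corrcoef(joined[0], joined[1])[0, 1])
        out.attrs["cor_with_h2_idm"] = cors
    return out
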