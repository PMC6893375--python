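"""Mixed-linear-model association scans for introgression-derived QTL.

Two scans share one machinery: per-SNP tests on allelic dosages (wild-
diagnostic-recoded at IDM sites, so effect signs read against the wild
allele) and window tests on mean diagnostic dosage (DoseGlaz). Population
and family structure is absorbed by a clone random effect with the
background (non-IDM) kinship; each predictor is tested as a fixed effect
and summarized by the Wald statistic (beta/se)^2 against chi-square(1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from . import reml
from .containers import DoseGlazMatrix, GenotypeMatrix, KinshipMatrix
from .models import ModelSpec, fit_reml
from .reml import RandomTerm

log = logging.getLogger(__name__)


def make_response(records: pd.DataFrame, trait: str, level: str = "multi_trial") -> pd.Series:
    """Per-clone BLUPs from an identity-covariance genetic model.

    Fits the IID model with the same design random effects as the
    multi-trial variance analysis; the clone BLUPs become the GWAS
    response. Clones with no records are absent.
    """
    spec = ModelSpec(trait=trait, model="IID", level=level)
    fit = fit_reml(records, spec)
    clones = fit.details["levels"]["g_iid"]
    return pd.Series(fit.blups["g_iid"], index=clones, name=trait)


def _null_mixed(y: np.ndarray, K: np.ndarray):
    """Estimate (sigma2_g, sigma2_e) under the no-predictor null and return
    the Cholesky of V = sigma2_g K + sigma2_e I."""
    X0 = np.ones((len(y), 1))
    term = RandomTerm("g", np.eye(len(y)), K)
    fit = reml.fit(y, X0, [term], want_blups=False)
    s2g, s2e = fit.sigma2["g"], fit.sigma2["residual"]
    V = s2g * K + s2e * np.eye(len(y))
    return fit, cho_factor(V, lower=True)


def _gls_test(y, x, cholV):
    """GLS fixed-effect test of x in y = mu + x beta + (structured noise)."""
    X = np.column_stack([np.ones(len(y)), x])
    ViX = cho_solve(cholV, X)
    Viy = cho_solve(cholV, y)
    XtViX = X.T @ ViX
    try:
        cov = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan, np.nan
    beta = cov @ (X.T @ Viy)
    se = np.sqrt(cov[1, 1])
    wald = (beta[1] / se) ** 2
    return float(beta[1]), float(se), float(wald), float(chi2.sf(wald, 1))


def snp_gwas(
    response: pd.Series,
    g: GenotypeMatrix,
    k_background: KinshipMatrix,
    maf_min: float = 0.05,
    exact: bool = False,
) -> pd.DataFrame:
    """Per-SNP mixed-model association scan.

    Variance components are estimated once under the no-SNP null and the
    resulting covariance reused for every test (the standard single-pass
    approximation); ``exact=True`` re-estimates them per SNP. SNPs with
    minor allele frequency below ``maf_min`` are excluded (counted in
    ``.attrs['n_excluded_maf']``). Missing dosages are mean-imputed per
    site for testing.
    """
    clones = [c for c in response.index if c in set(g.samples)]
    y = response[clones].to_numpy(dtype=float)
    gm = g.take_samples(clones)
    K = k_background.align(clones)
    null_fit, cholV = _null_mixed(y, K)

    p_hat = np.nanmean(gm.dosage, axis=0) / 2.0
    maf = np.minimum(p_hat, 1 - p_hat)
    testable = np.isfinite(maf) & (maf >= maf_min) & (maf > 0)
    n_excluded = int((~testable).sum())
    rows = []
    for j in np.flatnonzero(testable):
        x = gm.dosage[:, j].copy()
        x[~np.isfinite(x)] = 2 * p_hat[j]
        if exact:
            Xf = np.column_stack([np.ones(len(y)), x])
            term = RandomTerm("g", np.eye(len(y)), K)
            fitj = reml.fit(y, Xf, [term], want_blups=False)
            V = fitj.sigma2["g"] * K + fitj.sigma2["residual"] * np.eye(len(y))
            b, se, w, p = _gls_test(y, x, cho_factor(V, lower=True))
        else:
            b, se, w, p = _gls_test(y, x, cholV)
        rows.append(
            (gm.sites["chrom"].iloc[j], int(gm.sites["pos"].iloc[j]),
             gm.sites["id"].iloc[j], "snp", b, se, w, p, float(maf[j]))
        )
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "predictor_type", "effect", "se",
                       "wald", "p", "maf"]
    )
    out.attrs["n_excluded_maf"] = n_excluded
    out.attrs["null_fit"] = null_fit
    return out


def window_gwas(
    response: pd.Series,
    dose: DoseGlazMatrix,
    k_background: KinshipMatrix,
    min_idm: int = 1,
) -> pd.DataFrame:
    """Window mean-dosage association scan with the Wald statistic.

    Each window's DoseGlaz column is tested as a fixed effect in the same
    mixed model as the SNP scan. Windows with fewer than ``min_idm``
    markers or zero dosage variance are skipped (counted in
    ``.attrs['n_skipped']``).
    """
    clones = [c for c in response.index if c in set(dose.samples)]
    y = response[clones].to_numpy(dtype=float)
    sidx = [dose.samples.index(c) for c in clones]
    vals = dose.values[sidx, :]
    K = k_background.align(clones)
    null_fit, cholV = _null_mixed(y, K)

    rows = []
    n_skipped = 0
    for j in range(len(dose.windows)):
        if dose.windows["n_idm"].iloc[j] < min_idm:
            n_skipped += 1
            continue
        x = vals[:, j].copy()
        mu = np.nanmean(x)
        x[~np.isfinite(x)] = mu
        if not np.isfinite(mu) or np.nanstd(x) == 0:
            n_skipped += 1
            continue
        b, se, w, p = _gls_test(y, x, cholV)
        rows.append(
            (dose.windows["chrom"].iloc[j], int(dose.windows["start"].iloc[j]),
             int(dose.windows["end"].iloc[j]), "window", b, se, w, p, float(mu / 2.0))
        )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "predictor_type", "effect", "se",
                       "wald", "p", "mean_freq"]
    )
    out.attrs["n_skipped"] = n_skipped
    out.attrs["null_fit"] = null_fit
    return out


def window_dosage_by_count(mg_geno: GenotypeMatrix, idm_per_window: int = 15) -> DoseGlazMatrix:
    """Alternative windowing: fixed count of diagnostic markers per window.

    Consecutive runs of ``idm_per_window`` IDMs within a chromosome form
    one window spanning their positions (a trailing shorter run keeps its
    markers). Exposed for the fixed-count variant of the window scan;
    fixed-width 250-kb windows are the default elsewhere.
    """
    rows, cols = [], []
    chrom_arr = mg_geno.sites["chrom"].to_numpy()
    pos_arr = mg_geno.sites["pos"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        here = np.flatnonzero(chrom_arr == chrom)
        for s in range(0, here.size, idm_per_window):
            j = here[s : s + idm_per_window]
            rows.append((chrom, int(pos_arr[j].min()), int(pos_arr[j].max()) + 1, len(j)))
            cols.append(np.nanmean(mg_geno.dosage[:, j], axis=1))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_idm"])
    return DoseGlazMatrix(samples=list(mg_geno.samples), windows=windows,
                          values=np.column_stack(cols))


def bonferroni(p_values, m: int | None = None, alpha: float = 0.05):
    """Family-wise threshold alpha/m and strict-inequality significance flags."""
    p = np.asarray(p_values, dtype=float)
    m = m if m is not None else p.size
    if m < 1:
        raise ValueError("need at least one test")
    threshold = alpha / m
    return threshold, p < threshold
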