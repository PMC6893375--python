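"""Windowed introgression-dosage maps and per-individual/population summaries.

``window_dosage`` averages the wild-diagnostic allele dosage over the
diagnostic markers falling in fixed-width nonoverlapping windows (250 kb by
default), which smooths over individual genotyping errors and yields a
per-sample genome-wide map of introgression status.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import DoseGlazMatrix, GenotypeMatrix, RegionSpec, region_mask

log = logging.getLogger(__name__)


def window_dosage(mg_geno: GenotypeMatrix, width: int = 250_000) -> DoseGlazMatrix:
    """Mean wild-diagnostic dosage per sample in nonoverlapping windows.

    ``mg_geno`` must be restricted to IDM sites and recoded so the counted
    allele is the wild-diagnostic allele. Window w of a chromosome spans
    bp [1 + w*width, 1 + (w+1)*width); windows holding no markers are NaN.
    """
    if mg_geno.n_sites == 0:
        raise ValueError("no diagnostic sites supplied")
    win_rows = []
    cols = []
    chrom_arr = mg_geno.sites["chrom"].to_numpy()
    pos_arr = mg_geno.sites["pos"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        here = np.flatnonzero(chrom_arr == chrom)
        widx = (pos_arr[here] - 1) // width
        for w in range(int(widx.max()) + 1):
            j = here[widx == w]
            start = 1 + w * width
            win_rows.append((chrom, start, start + width, len(j)))
            if len(j):
                cols.append(np.nanmean(mg_geno.dosage[:, j], axis=1))
            else:
                cols.append(np.full(mg_geno.n_samples, np.nan))
    windows = pd.DataFrame(win_rows, columns=["chrom", "start", "end", "n_idm"])
    return DoseGlazMatrix(
        samples=list(mg_geno.samples), windows=windows, values=np.column_stack(cols)
    )


def _region_sites(mg_geno: GenotypeMatrix, region: RegionSpec | None) -> np.ndarray:
    if region is None:
        return np.arange(mg_geno.n_sites)
    idx = np.flatnonzero(region_mask(mg_geno.sites, [region]))
    if idx.size == 0:
        log.warning("region %s holds no diagnostic sites", region.label or region.chrom)
    return idx


def individual_proportion(mg_geno: GenotypeMatrix, region: RegionSpec | None = None) -> pd.Series:
    """Per-individual proportion of wild-diagnostic alleles in a region:
    sum of IDM dosages / (2 * number of IDMs)."""
    idx = _region_sites(mg_geno, region)
    if idx.size == 0:
        return pd.Series(np.nan, index=mg_geno.samples)
    d = mg_geno.dosage[:, idx]
    with np.errstate(invalid="ignore"):
        prop = np.nansum(d, axis=1) / (2.0 * np.sum(np.isfinite(d), axis=1))
    return pd.Series(prop, index=mg_geno.samples)


def homozygosity_rate(mg_geno: GenotypeMatrix, region: RegionSpec | None = None) -> pd.Series:
    """Per-individual fraction of region IDMs whose rounded dosage is 2."""
    idx = _region_sites(mg_geno, region)
    if idx.size == 0:
        return pd.Series(np.nan, index=mg_geno.samples)
    hard = np.round(mg_geno.dosage[:, idx])
    n = np.sum(np.isfinite(hard), axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        rate = np.nansum(hard == 2, axis=1) / n
    return pd.Series(rate, index=mg_geno.samples)


def population_compare(
    mg_geno: GenotypeMatrix,
    populations: pd.Series,
    regions: dict[str, RegionSpec | None],
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Group means of introgression summaries per population x region.

    ``populations`` maps sample id -> population label; ``regions`` maps a
    region label to a :class:`RegionSpec` (None = genome-wide). Samples in
    ``exclude`` (e.g. known outliers) are removed before averaging.
    Returns a tidy table with the mean per-individual proportion, mean
    homozygosity rate and mean per-IDM wild-allele frequency.
    """
    unknown = set(populations.index) - set(mg_geno.samples)
    if unknown:
        raise ValueError(f"population labels for unknown samples: {sorted(unknown)[:5]}")
    exclude = set(exclude or [])
    rows = []
    for rlabel, region in regions.items():
        prop = individual_proportion(mg_geno, region)
        hom = homozygosity_rate(mg_geno, region)
        idx = _region_sites(mg_geno, region)
        for pop in populations.unique():
            ids = [s for s in populations.index[populations == pop] if s not in exclude]
            if not ids:
                continue
            sub = mg_geno.sample_index(ids)
            freq = (
                np.nanmean(mg_geno.dosage[np.ix_(sub, idx)], axis=0) / 2.0
                if idx.size
                else np.array([])
            )
            rows.append(
                (pop, rlabel, len(ids), prop[ids].mean(), hom[ids].mean(),
                 float(np.nanmean(freq)) if freq.size else np.nan)
            )
    return pd.DataFrame(
        rows,
        columns=["population", "region", "n", "mean_proportion", "mean_homozygosity",
                 "mean_idm_freq"],
    )


def pca(g: GenotypeMatrix, maf_min: float = 0.01, n_components: int | None = None):
    """PCA of center+scale standardized dosages.

    Sites with minor allele frequency <= ``maf_min`` are removed; missing
    dosages are mean-imputed per site before scaling. Each component's
    loading vector is sign-flipped so its largest-magnitude loading is
    positive. Returns ``(scores, loadings, var_explained, site_index)``.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = g.dosage.astype(float).copy()
    p = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = np.flatnonzero(np.isfinite(maf) & (maf > maf_min))
    if keep.size < 2:
        raise ValueError("fewer than 2 polymorphic sites after MAF filter")
    X = X[:, keep]
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    sd = X.std(axis=0, ddof=1)
    Z = (X - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k = n_components or min(Z.shape) - 1 or 1
    k = min(k, S.size)
    sign = np.sign(Vt[np.arange(S.size), np.argmax(np.abs(Vt), axis=1)])
    sign[sign == 0] = 1.0
    Vt = Vt * sign[:, None]
    U = U * sign[None, :]
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    var_explained = (S**2) / np.sum(S**2)
    return scores, loadings, var_explained[:k], keep


def genetic_load(
    del_geno: GenotypeMatrix,
    regions: dict[str, RegionSpec | None],
    populations: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-individual deleterious-allele burden, per region and genome-wide.

    ``del_geno`` counts the deleterious allele. ``total_load`` is the summed
    dosage; ``hom_load`` the count of sites with rounded dosage 2. When
    ``populations`` is given, per-population means and the percent change
    between consecutive labels (in the order given) are appended as a second
    table attribute ``.attrs['group_change']``.
    """
    rows = []
    for rlabel, region in regions.items():
        idx = _region_sites(del_geno, region)
        d = del_geno.dosage[:, idx] if idx.size else np.zeros((del_geno.n_samples, 0))
        total = np.nansum(d, axis=1)
        hom = np.nansum(np.round(d) == 2, axis=1)
        for i, s in enumerate(del_geno.samples):
            rows.append((s, rlabel, total[i], int(hom[i])))
    out = pd.DataFrame(rows, columns=["sample", "region", "total_load", "hom_load"])
    if populations is not None:
        out["population"] = out["sample"].map(populations)
        g = out.groupby(["region", "population"], sort=False)[["total_load", "hom_load"]].mean()
        order = list(dict.fromkeys(populations))
        change = []
        for region in regions:
            for a, b in zip(order[:-1], order[1:]):
                for col in ("total_load", "hom_load"):
                    va = g.loc[(region, a), col]
                    vb = g.loc[(region, b), col]
                    pct = 100.0 * (vb - va) / va if va else np.nan
                    change.append((region, f"{a}->{b}", col, va, vb, pct))
        out.attrs["group_change"] = pd.DataFrame(
            change, columns=["region", "transition", "measure", "from", "to", "pct_change"]
        )
    return out


def advancement_summary(
    homozygosity: pd.Series,
    proportion: pd.Series,
    plot_counts: pd.Series,
    threshold: int = 50,
) -> pd.DataFrame:
    """Join per-clone introgression summaries with field-plot counts.

    Clones with more than ``threshold`` cumulative plots are flagged as
    advanced; unmatched ids are listed in ``.attrs['unmatched']`` and
    excluded.
    """
    ids = sorted(set(homozygosity.index) & set(plot_counts.index) & set(proportion.index))
    unmatched = sorted(
        (set(homozygosity.index) | set(plot_counts.index) | set(proportion.index)) - set(ids)
    )
    if not ids:
        log.warning("no overlapping ids between summaries and plot counts")
    out = pd.DataFrame(
        {
            "clone": ids,
            "proportion": proportion[ids].to_numpy(),
            "homozygosity": homozygosity[ids].to_numpy(),
            "plot_count": plot_counts[ids].to_numpy(),
        }
    )
    out["advanced"] = out["plot_count"] > threshold
    out.attrs["unmatched"] = unmatched
    return out
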