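"""The genetic-variance model suite, trial curation and heritability partition.

Six models are fitted per trait dataset, differing only in their genetic
random term(s):

- NULL: no genetic term (design randoms only)
- IID: clone effect with identity covariance
- ALL: clone effect with the all-marker kinship
- IDM: clone effect with the introgression-partition kinship (IDM + tag-IDM)
- IDMnull: clone effect with the background (non-IDM) kinship
- PARTITIONED: two clone effects, one per kinship

All models share fixed effects (intercept, plus NOHAV for plot-level yield
traits) so their restricted likelihoods are comparable; per-trial fits add
replication (and optionally block-within-rep) identity randoms, multi-trial
fits add location-year-trial and location-year-trial-rep identity randoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reml
from .containers import KinshipMatrix, check_phenotypes
from .reml import RandomTerm, VarCompFit, aic, lrt

log = logging.getLogger(__name__)

YIELD_TRAITS = ("RTWT", "RTNO", "SHTWT")  # ln-transformed, NOHAV fixed effect
LOG_TRAITS = YIELD_TRAITS

GENETIC_MODELS = ("IID", "ALL", "IDM", "IDMnull", "PARTITIONED")
GENOMIC_MODELS = ("ALL", "IDM", "IDMnull", "PARTITIONED")


@dataclass
class ModelSpec:
    """Declarative description of one mixed model for one trait."""

    trait: str
    model: str  # one of NULL / IID / ALL / IDM / IDMnull / PARTITIONED
    level: str = "per_trial"  # or "multi_trial"
    use_nohav: bool | None = None  # default: trait in YIELD_TRAITS
    log_transform: bool | None = None  # default: trait in LOG_TRAITS
    block_nested: bool = False  # block-within-rep random (program-specific)

    def __post_init__(self) -> None:
        if self.use_nohav is None:
            self.use_nohav = self.trait in YIELD_TRAITS
        if self.log_transform is None:
            self.log_transform = self.trait in LOG_TRAITS


def _incidence(labels: pd.Series):
    levels = pd.unique(labels)
    lookup = {v: i for i, v in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [lookup[v] for v in labels]] = 1.0
    return Z, list(levels)


def _prepare(records: pd.DataFrame, spec: ModelSpec):
    rec = check_phenotypes(records)
    rec = rec[rec["trait"] == spec.trait].copy()
    rec = rec[np.isfinite(rec["value"])]
    if spec.log_transform:
        bad = rec["value"] <= 0
        if bad.any():
            log.info("dropping %d non-positive records before ln transform", int(bad.sum()))
            rec = rec[~bad]
        rec["value"] = np.log(rec["value"])
    if rec.empty:
        raise ValueError(f"no records for trait {spec.trait!r}")
    y = rec["value"].to_numpy(dtype=float)
    cols = [np.ones(len(rec))]
    if spec.use_nohav:
        nohav = rec["nohav"].to_numpy(dtype=float)
        if np.isfinite(nohav).all():
            cols.append(nohav)
        else:
            log.warning("NOHAV missing for trait %s; fitting without it", spec.trait)
    X = np.column_stack(cols)
    return rec, y, X


def _design_randoms(rec: pd.DataFrame, spec: ModelSpec) -> list[RandomTerm]:
    terms = []
    if spec.level == "per_trial":
        if rec["rep"].notna().any() and rec["rep"].nunique() > 1:
            Z, lv = _incidence(rec["rep"].astype(str))
            terms.append(RandomTerm("rep", Z, None, lv))
            if spec.block_nested and rec["block"].notna().any():
                lbl = rec["rep"].astype(str) + ":" + rec["block"].astype(str)
                if lbl.nunique() > rec["rep"].nunique():
                    Zb, lvb = _incidence(lbl)
                    terms.append(RandomTerm("block", Zb, None, lvb))
    else:
        lyt = rec["loc_year"].astype(str) + ":" + rec["trial"].astype(str)
        if lyt.nunique() > 1:
            Z, lv = _incidence(lyt)
            terms.append(RandomTerm("loc_yr_trial", Z, None, lv))
        lytr = lyt + ":" + rec["rep"].astype(str)
        if lytr.nunique() > lyt.nunique():
            Z, lv = _incidence(lytr)
            terms.append(RandomTerm("loc_yr_trial_rep", Z, None, lv))
    return terms


def _genetic_terms(rec: pd.DataFrame, model: str, kinships: dict) -> list[RandomTerm]:
    Z, clones = _incidence(rec["clone"].astype(str))

    def kin(key: str) -> np.ndarray:
        k = kinships[key]
        if not isinstance(k, KinshipMatrix):
            raise TypeError(f"kinships[{key!r}] must be a KinshipMatrix")
        return k.align(clones)

    if model == "NULL":
        return []
    if model == "IID":
        return [RandomTerm("g_iid", Z, None, clones)]
    if model == "ALL":
        return [RandomTerm("g_all", Z, kin("all"), clones)]
    if model == "IDM":
        return [RandomTerm("g_idm", Z, kin("idm"), clones)]
    if model == "IDMnull":
        return [RandomTerm("g_nonidm", Z, kin("non_idm"), clones)]
    if model == "PARTITIONED":
        return [
            RandomTerm("g_idm", Z, kin("idm"), clones),
            RandomTerm("g_nonidm", Z, kin("non_idm"), clones),
        ]
    raise ValueError(f"unknown model {model!r}")


def fit_reml(
    records: pd.DataFrame,
    spec: ModelSpec,
    kinships: dict | None = None,
    want_pev: bool = False,
) -> VarCompFit:
    """Fit one model of the suite to phenotype records by REML."""
    rec, y, X = _prepare(records, spec)
    terms = _genetic_terms(rec, spec.model, kinships or {}) + _design_randoms(rec, spec)
    fit = reml.fit(y, X, terms, want_pev=want_pev)
    fit.details["model"] = spec.model
    fit.details["trait"] = spec.trait
    return fit


def model_suite(
    records: pd.DataFrame,
    kinships: dict,
    trait: str,
    level: str = "per_trial",
    models=("NULL", "IID", "ALL", "IDM", "IDMnull", "PARTITIONED"),
    block_nested: bool = False,
    want_pev: bool = False,
) -> dict[str, VarCompFit]:
    """Fit the model suite for one trait dataset.

    ``kinships`` must provide keys ``all``, ``idm`` and ``non_idm`` for the
    corresponding models. Returns a mapping model name -> fit; the
    partition LRT (PARTITIONED vs IDMnull) is attached to the PARTITIONED
    fit under ``details['lrt_partition']``.
    """
    fits = {}
    for m in models:
        spec = ModelSpec(trait=trait, model=m, level=level, block_nested=block_nested)
        fits[m] = fit_reml(records, spec, kinships, want_pev=want_pev)
    if "NULL" in fits:
        for m in GENETIC_MODELS:
            if m in fits:
                stat, df, p = lrt(fits[m], fits["NULL"])
                fits[m].details["lrt_null"] = {"stat": stat, "df": df, "p": p}
    if "PARTITIONED" in fits and "IDMnull" in fits:
        stat, df, p = lrt(fits["PARTITIONED"], fits["IDMnull"])
        fits["PARTITIONED"].details["lrt_partition"] = {"stat": stat, "df": df, "p": p}
    return fits


def curate_trials(per_trial_fits: dict) -> pd.DataFrame:
    """Keep/drop decisions for trait-trial datasets from their model fits.

    ``per_trial_fits`` maps (trait, trial) -> {model: VarCompFit}. A
    trait-trial is dropped when (1) no genetic model beats NULL at
    p < 0.05, else (2) no genomic (kinship) model beats NULL at p < 0.05,
    else (3) the IID model's AIC is at least 2 units below the best
    genomic AIC.
    """
    rows = []
    for (trait, trial), fits in per_trial_fits.items():
        for m in ("NULL", "IID"):
            if m not in fits:
                raise ValueError(f"trait-trial ({trait}, {trial}) missing {m} fit")
        if not any(m in fits for m in GENOMIC_MODELS):
            raise ValueError(f"trait-trial ({trait}, {trial}) has no genomic fit")
        p_gen = {m: fits[m].details["lrt_null"]["p"] for m in GENETIC_MODELS if m in fits}
        p_genomic = {m: p_gen[m] for m in GENOMIC_MODELS if m in p_gen}
        aic_iid = fits["IID"].aic
        aic_genomic = min(fits[m].aic for m in GENOMIC_MODELS if m in fits)
        if not any(p < 0.05 for p in p_gen.values()):
            keep, reason = False, "rule1_no_genetic_signal"
        elif not any(p < 0.05 for p in p_genomic.values()):
            keep, reason = False, "rule2_no_genomic_signal"
        elif aic_iid <= aic_genomic - 2.0:
            keep, reason = False, "rule3_iid_better_by_2_aic"
        else:
            keep, reason = True, ""
        rows.append(
            (trait, trial, min(p_gen.values()), min(p_genomic.values()),
             aic_iid, aic_genomic, keep, reason)
        )
    return pd.DataFrame(
        rows,
        columns=["trait", "trial", "min_p_genetic", "min_p_genomic", "aic_iid",
                 "aic_best_genomic", "keep", "drop_reason"],
    )


@dataclass
class HeritabilityPartition:
    h2_idm: float
    h2_nonidm: float
    h2_total: float
    share: float


def heritability(fit: VarCompFit, include_design: bool = False) -> HeritabilityPartition:
    """Partition heritability from a fitted model.

    h2_x = sigma2_x / (sum of genetic variances + residual). Design
    variances (rep, block, location-year terms) are excluded from the
    denominator by default; pass ``include_design=True`` to add them.
    """
    genetic = {k: v for k, v in fit.sigma2.items() if k.startswith("g_")}
    if not genetic:
        raise ValueError("fit has no genetic variance component")
    denom = sum(genetic.values()) + fit.sigma2["residual"]
    if include_design:
        denom += sum(v for k, v in fit.sigma2.items()
                     if not k.startswith("g_") and k != "residual")
    if denom == 0:
        log.warning("all variance components zero; heritability undefined")
        return HeritabilityPartition(np.nan, np.nan, np.nan, np.nan)
    h2_idm = genetic.get("g_idm", 0.0) / denom
    h2_non = sum(v for k, v in genetic.items() if k != "g_idm") / denom
    h2_tot = h2_idm + h2_non
    share = h2_idm / h2_tot if h2_tot > 0 else np.nan
    return HeritabilityPartition(h2_idm, h2_non, h2_tot, share)


def random_partition_controls(
    records: pd.DataFrame,
    trait: str,
    geno,
    partitions,
    idm_kinships: dict | None = None,
    level: str = "multi_trial",
) -> pd.DataFrame:
    """PARTITIONED fits under random genome partitions of IDM-equivalent size.

    Each :class:`~wildintro.tagging.GenomePartition` in ``partitions``
    yields a two-kinship fit; shares, partition LRTs and AICs are tabulated
    against the IDM-defined partition (fitted from ``idm_kinships`` when
    given). Random shares should sit near the marker-count proportion under
    a uniformly polygenic trait, unlike a partition capturing localized
    causal variation.
    """
    from .kinship import make_grm

    rows = []

    def one(label, kin):
        fits = model_suite(records, kin, trait, level=level,
                           models=("IDMnull", "PARTITIONED"))
        part = fits["PARTITIONED"]
        h = heritability(part)
        lp = part.details["lrt_partition"]
        rows.append((label, h.h2_idm, h.h2_nonidm, h.share, lp["stat"], lp["p"], part.aic))

    if idm_kinships is not None:
        one("idm_defined", idm_kinships)
    for i, p in enumerate(partitions):
        kin = {
            "idm": make_grm(geno.take_sites(p.idm_plus_tag), method_tag="random_idm_like"),
            "non_idm": make_grm(geno.take_sites(p.non_idm), method_tag="random_rest"),
        }
        one(p.provenance or f"random_{i}", kin)
    return pd.DataFrame(
        rows,
        columns=["partition", "h2_idm", "h2_nonidm", "share", "lrt_stat", "lrt_p", "aic"],
    )
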