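"""Synthetic data with the genetic structure of a wild-introgression study.

The generator emulates two diverged *Manihot*-like populations (a small
wild panel and a cultivated pool), hybridization followed by repeated
backcrossing to the cultivated side, recombination suppression inside
designated introgression regions, optional random mating with truncation
selection on regional wild-allele dosage, polygenic traits whose
plot-basis heritability is split between introgressed and background
regions, multi-trial field designs, genotyping noise, and deleterious
load enriched on introgressed haplotypes.

Sites are SNPs of an ascertained panel: neutral sites are conditioned on
remaining polymorphic within the cultivated pool (no random subset of
panel size is fixed), so on noiseless data the diagnostic-marker rules
recover the annotated fixed-difference and wild-private sites exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, GeneticMap, RegionSpec, region_mask

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic introgression population."""

    n_mg: int = 8
    n_me: int = 25
    n_admixed: int = 100
    chromosomes: dict = field(
        default_factory=lambda: {"chr1": 35_000_000, "chr4": 30_000_000}
    )
    cm_per_mb: float = 3.0
    n_sites: int = 4000
    fixed_difference_fraction: float = 0.02
    mg_private_poly_fraction: float = 0.02
    divergence_F: float = 0.2
    regions: list = field(
        default_factory=lambda: [
            RegionSpec("chr1", 25_000_001, 35_000_001, "chr1_distal"),
            RegionSpec("chr4", 5_000_001, 25_000_001, "chr4_core"),
        ]
    )
    # map-compression multiplier inside each region (order matches regions);
    # 0.86 and 0.29 reproduce 14% and 71% recombination reductions
    suppression: list = field(default_factory=lambda: [0.86, 0.29])
    backcross_depth: int = 3
    random_mating_generations: int = 0
    selection_fraction: float | None = None  # truncation on region wild dosage
    selection_region: int = 0  # index into regions
    seed: int = 1


@dataclass
class TraitConfig:
    """Genetic architecture and trial design for one synthetic trait."""

    name: str = "TRAIT"
    n_causal_idm: int = 20
    n_causal_bg: int = 80
    h2_idm: float = 0.2
    h2_nonidm: float = 0.4
    v_trial: float = 0.25
    v_rep: float = 0.1
    n_trials: int = 2
    n_reps: int = 1
    nohav_mean: float | None = None  # Poisson mean; None = no NOHAV column
    nohav_effect: float = 0.0
    exact_scale: bool = True  # scale effects to realized (not expected) variance


@dataclass
class SimTruth:
    """Ground truth: local ancestry, causal effects, variance components."""

    ancestry: np.ndarray  # samples x sites, wild-haplotype count 0/1/2
    generation: pd.Series  # per-sample cohort label
    site_class: pd.Series  # fixed_diff / mg_private / neutral
    mg_allele: pd.Series  # 'ref' or 'alt' for diagnostic-class sites
    cm_pos: np.ndarray
    causal: pd.DataFrame | None = None
    components: dict | None = None


def _site_scaffold(cfg: SimConfig, rng) -> pd.DataFrame:
    lengths = np.array(list(cfg.chromosomes.values()), dtype=float)
    counts = np.maximum(1, np.round(cfg.n_sites * lengths / lengths.sum()).astype(int))
    rows = []
    for (chrom, L), m in zip(cfg.chromosomes.items(), counts):
        pos = np.sort(rng.choice(np.arange(1, int(L) + 1), size=m, replace=False))
        for p in pos:
            rows.append((chrom, int(p)))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df["id"] = df["chrom"].astype(str) + "_" + df["pos"].astype(str)
    df["ref"] = "A"
    df["alt"] = "B"
    df["counted_allele"] = "alt"
    return df


def _cm_positions(cfg: SimConfig, sites: pd.DataFrame) -> np.ndarray:
    """Genetic position of each site under region map compression."""
    cm = np.empty(len(sites))
    for chrom in sites["chrom"].unique():
        here = sites["chrom"] == chrom
        pos = sites.loc[here, "pos"].to_numpy(dtype=float)
        rate = np.full(len(pos), cfg.cm_per_mb / 1e6)
        for r, f in zip(cfg.regions, cfg.suppression):
            if r.chrom == chrom:
                inside = (pos >= r.start) & (pos < r.end)
                rate[inside] *= f
        # piecewise-linear cumulative map from per-interval rates
        edges = np.concatenate([[0.0], pos])
        seg_rate = np.concatenate([[cfg.cm_per_mb / 1e6], rate])
        cm[np.flatnonzero(here.to_numpy())] = np.cumsum(np.diff(edges) * seg_rate[1:])
    return cm


def genetic_map_from_truth(cfg: SimConfig, sites: pd.DataFrame, truth_cm: np.ndarray,
                           n_anchors_per_chrom: int = 60) -> GeneticMap:
    """Thin the true site map into an anchor-marker genetic map."""
    rows = []
    for chrom in sites["chrom"].unique():
        idx = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        pick = idx[np.unique(np.linspace(0, idx.size - 1, n_anchors_per_chrom).astype(int))]
        for j in pick:
            rows.append((chrom, int(sites["pos"].iloc[j]), float(truth_cm[j])))
    return GeneticMap(anchors=pd.DataFrame(rows, columns=["chrom", "pos", "cM"]))


def simulate_founders(cfg: SimConfig):
    """Draw wild and cultivated founder haplotypes with annotated site classes.

    Returns ``(mg_geno, me_geno, site_class, mg_allele, mg_haps, me_haps,
    sites)``. Fixed-difference sites are fixed for opposite alleles in the
    two populations; wild-private sites are fixed in the cultivated pool
    and polymorphic in the realized wild panel; neutral sites follow a
    Balding-Nichols divergence model conditioned on panel polymorphism.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    sites = _site_scaffold(cfg, rng)
    m = len(sites)
    n_fd = int(round(cfg.fixed_difference_fraction * m))
    n_gp = int(round(cfg.mg_private_poly_fraction * m))
    classes = np.array(["neutral"] * m, dtype=object)
    special = rng.choice(m, size=n_fd + n_gp, replace=False)
    classes[special[:n_fd]] = "fixed_diff"
    classes[special[n_fd:]] = "mg_private"
    mg_allele = np.array([None] * m, dtype=object)

    mg_h = np.empty((2 * cfg.n_mg, m), dtype=np.int8)
    me_h = np.empty((2 * cfg.n_me, m), dtype=np.int8)
    F = cfg.divergence_F
    a = (1 - F) / F
    max_hom = min(10, cfg.n_me) - 1  # no panel-sized subset may be fixed
    for j in range(m):
        cls = classes[j]
        if cls == "fixed_diff":
            wild_is_alt = rng.random() < 0.5
            mg_h[:, j] = 1 if wild_is_alt else 0
            me_h[:, j] = 0 if wild_is_alt else 1
            mg_allele[j] = "alt" if wild_is_alt else "ref"
        elif cls == "mg_private":
            wild_is_alt = rng.random() < 0.5
            me_h[:, j] = 0 if wild_is_alt else 1
            mg_allele[j] = "alt" if wild_is_alt else "ref"
            while True:
                q = rng.uniform(0.2, 0.8)
                hap = rng.random(2 * cfg.n_mg) < q
                if hap.any() and not hap.all():
                    break
            mg_h[:, j] = np.where(hap, 1, 0) if wild_is_alt else np.where(hap, 0, 1)
        else:
            while True:
                p_anc = rng.uniform(0.3, 0.7)
                p_me = rng.beta(a * p_anc, a * (1 - p_anc))
                p_mg = rng.beta(a * p_anc, a * (1 - p_anc))
                if not 0.2 <= p_me <= 0.8:
                    continue
                me_col = (rng.random(2 * cfg.n_me) < p_me).astype(np.int8)
                dose = me_col[0::2] + me_col[1::2]
                if (dose == 0).sum() <= max_hom and (dose == 2).sum() <= max_hom:
                    break
            me_h[:, j] = me_col
            mg_h[:, j] = (rng.random(2 * cfg.n_mg) < p_mg).astype(np.int8)

    mg_geno = GenotypeMatrix(
        samples=[f"MG{i:02d}" for i in range(cfg.n_mg)],
        sites=sites.copy(),
        dosage=(mg_h[0::2] + mg_h[1::2]).astype(float),
    )
    me_geno = GenotypeMatrix(
        samples=[f"ME{i:02d}" for i in range(cfg.n_me)],
        sites=sites.copy(),
        dosage=(me_h[0::2] + me_h[1::2]).astype(float),
    )
    return (
        mg_geno,
        me_geno,
        pd.Series(classes, name="site_class"),
        pd.Series(mg_allele, name="mg_allele"),
        mg_h,
        me_h,
        sites,
    )


def _gamete(hapA, hapB, ancA, ancB, cm, chrom_of, rng):
    """Meiosis under a Haldane (no-interference) crossover model.

    Crossover counts per chromosome are Poisson in its genetic length;
    crossover locations are uniform on the cM scale, so map compression
    inside introgressions directly suppresses recombination there.
    """
    out_h = np.empty_like(hapA)
    out_a = np.empty_like(ancA)
    for chrom in np.unique(chrom_of):
        idx = np.flatnonzero(chrom_of == chrom)
        c = cm[idx]
        length = c[-1] - c[0]
        n_cx = rng.poisson(length / 100.0)
        cuts = np.sort(rng.uniform(c[0], c[-1], size=n_cx))
        phase = int(rng.integers(2)) + np.searchsorted(cuts, c, side="right")
        use_a = phase % 2 == 0
        out_h[idx] = np.where(use_a, hapA[idx], hapB[idx])
        out_a[idx] = np.where(use_a, ancA[idx], ancB[idx])
    return out_h, out_a


def simulate_admixed(cfg: SimConfig, founders) -> tuple[GenotypeMatrix, SimTruth]:
    """Breed an admixed cohort: F1, backcrosses, optional random mating.

    Each admixed individual descends from an independent F1 (one wild, one
    cultivated founder gamete) backcrossed ``backcross_depth`` times to
    random cultivated founders. With ``random_mating_generations > 0`` the
    final backcross cohort is random-mated forward, optionally truncating
    parents on their wild-allele dosage in ``selection_region``
    (``selection_fraction`` kept). All cohorts are returned, labeled by
    generation.
    """
    mg_geno, me_geno, site_class, mg_allele, mg_h, me_h, sites = founders
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    cm = _cm_positions(cfg, sites)
    chrom_of = sites["chrom"].to_numpy()
    m = len(sites)
    if cfg.n_admixed < 1:
        raise ValueError("pedigree empty: n_admixed must be >= 1")

    def me_gamete():
        i = int(rng.integers(cfg.n_me))
        return _gamete(me_h[2 * i], me_h[2 * i + 1], np.zeros(m, np.int8),
                       np.zeros(m, np.int8), cm, chrom_of, rng)

    def mg_gamete():
        i = int(rng.integers(cfg.n_mg))
        return _gamete(mg_h[2 * i], mg_h[2 * i + 1], np.ones(m, np.int8),
                       np.ones(m, np.int8), cm, chrom_of, rng)

    cohort = []  # list of (hapA, hapB, ancA, ancB)
    for _ in range(cfg.n_admixed):
        hA, aA = mg_gamete()
        hB, aB = me_gamete()
        for _ in range(cfg.backcross_depth):
            hA, aA = _gamete(hA, hB, aA, aB, cm, chrom_of, rng)
            hB, aB = me_gamete()
        cohort.append((hA, hB, aA, aB))

    cohorts = [(f"BC{cfg.backcross_depth}", cohort)]
    region = cfg.regions[cfg.selection_region] if cfg.regions else None
    rmask = region_mask(sites, [region]) if region is not None else None
    for gen in range(1, cfg.random_mating_generations + 1):
        parents = cohorts[-1][1]
        if cfg.selection_fraction is not None and rmask is not None:
            score = [((aA + aB)[rmask]).mean() for _, _, aA, aB in parents]
            n_keep = max(2, int(np.ceil(cfg.selection_fraction * len(parents))))
            keep = np.argsort(score)[::-1][:n_keep]
            pool = [parents[i] for i in keep]
        else:
            pool = parents
        nxt = []
        for _ in range(cfg.n_admixed):
            i, j = rng.integers(len(pool)), rng.integers(len(pool))
            hA, aA = _gamete(pool[i][0], pool[i][1], pool[i][2], pool[i][3],
                             cm, chrom_of, rng)
            hB, aB = _gamete(pool[j][0], pool[j][1], pool[j][2], pool[j][3],
                             cm, chrom_of, rng)
            nxt.append((hA, hB, aA, aB))
        cohorts.append((f"G{gen}", nxt))

    samples, gen_labels, dosage, ancestry = [], [], [], []
    for label, members in cohorts:
        for i, (hA, hB, aA, aB) in enumerate(members):
            samples.append(f"{label}_{i:03d}")
            gen_labels.append(label)
            dosage.append((hA + hB).astype(float))
            ancestry.append(aA + aB)
    geno = GenotypeMatrix(samples=samples, sites=sites.copy(),
                          dosage=np.asarray(dosage))
    truth = SimTruth(
        ancestry=np.asarray(ancestry, dtype=np.int8),
        generation=pd.Series(gen_labels, index=samples),
        site_class=site_class,
        mg_allele=mg_allele,
        cm_pos=cm,
    )
    return geno, truth


def simulate_phenotypes(
    cfg: SimConfig, trait: TraitConfig, geno: GenotypeMatrix, truth: SimTruth,
    seed: int | None = None,
) -> pd.DataFrame:
    """Plot-level phenotype records for the admixed cohort.

    Clone genetic value is the sum of causal effects at sites inside
    introgression regions (acting on local wild-haplotype count, hence
    attributable to the introgression partition) and at neutral background
    sites outside them. Effects are scaled so the plot-basis variance
    shares hit ``h2_idm`` / ``h2_nonidm`` (exactly on the realized sample
    by default, in expectation with ``exact_scale=False``); total
    phenotypic plot variance excluding design effects is 1. Trial and rep
    effects and, optionally, a NOHAV covariate effect are added per plot.
    """
    if trait.h2_idm + trait.h2_nonidm >= 1:
        raise ValueError("h2 targets must sum to < 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 37])
    )
    n = geno.n_samples
    in_region = region_mask(geno.sites, cfg.regions)
    fd = (truth.site_class == "fixed_diff").to_numpy()
    neutral = (truth.site_class == "neutral").to_numpy()

    def component(pool_mask, n_causal, target_var, use_ancestry):
        if target_var <= 0 or n_causal == 0:
            return np.zeros(n), pd.DataFrame(columns=["site_index", "effect"])
        pool = np.flatnonzero(pool_mask)
        if pool.size == 0:
            raise ValueError("no candidate causal sites in requested pool")
        picked = rng.choice(pool, size=min(n_causal, pool.size), replace=False)
        X = truth.ancestry[:, picked].astype(float) if use_ancestry else geno.dosage[:, picked]
        X = X - X.mean(axis=0)
        a = rng.normal(size=picked.size)
        g = X @ a
        v = g.var()
        if trait.exact_scale:
            if v == 0:
                raise ValueError("causal genotypes carry no variance")
            scale = np.sqrt(target_var / v)
        else:
            ev = float(np.sum(X.var(axis=0)))
            scale = np.sqrt(target_var / ev) if ev > 0 else 0.0
        return g * scale, pd.DataFrame({"site_index": picked, "effect": a * scale})

    g_idm, causal_idm = component(in_region & fd, trait.n_causal_idm,
                                  trait.h2_idm, use_ancestry=True)
    g_bg, causal_bg = component(~in_region & neutral, trait.n_causal_bg,
                                trait.h2_nonidm, use_ancestry=False)
    s2e = 1.0 - trait.h2_idm - trait.h2_nonidm

    rows = []
    for t in range(1, trait.n_trials + 1):
        t_eff = rng.normal(0, np.sqrt(trait.v_trial))
        for r in range(1, trait.n_reps + 1):
            r_eff = rng.normal(0, np.sqrt(trait.v_rep)) if trait.n_reps > 1 else 0.0
            nohav = (
                rng.poisson(trait.nohav_mean, size=n).astype(float)
                if trait.nohav_mean is not None
                else np.full(n, np.nan)
            )
            e = rng.normal(0, np.sqrt(s2e), size=n)
            val = g_idm + g_bg + t_eff + r_eff + e
            if trait.nohav_mean is not None:
                val = val + trait.nohav_effect * (nohav - trait.nohav_mean)
            for i, clone in enumerate(geno.samples):
                rows.append(
                    (clone, trait.name, val[i], f"T{t}", f"LY{t}", f"R{r}", "B1",
                     nohav[i])
                )
    records = pd.DataFrame(
        rows,
        columns=["clone", "trait", "value", "trial", "loc_year", "rep", "block",
                 "nohav"],
    )
    pieces = [
        df.assign(partition=lbl)
        for df, lbl in ((causal_idm, "idm"), (causal_bg, "background"))
        if not df.empty
    ]
    truth.causal = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(columns=["site_index", "effect", "partition"])
    )
    truth.components = {
        "h2_idm": trait.h2_idm,
        "h2_nonidm": trait.h2_nonidm,
        "sigma2_e": s2e,
        "genetic_value": g_idm + g_bg,
        "g_idm": g_idm,
        "g_bg": g_bg,
    }
    return records


def simulate_deleterious(
    cfg: SimConfig, truth: SimTruth, geno: GenotypeMatrix,
    n_del: int = 200, base_rate: float = 0.05, enrichment: float = 3.0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Deleterious-allele dosages with excess load on introgressed haplotypes.

    At each deleterious site inside an introgression region, a haplotype
    carries the deleterious allele with probability ``base_rate`` when of
    cultivated ancestry and ``base_rate * enrichment`` when wild-derived;
    outside the regions both ancestries carry it at ``base_rate``.
    Carrier status is drawn per haplotype conditional on local ancestry
    (identity-by-descent correlation between relatives is not modeled).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 53])
    )
    if n_del == 0:
        return GenotypeMatrix(samples=list(geno.samples),
                              sites=geno.sites.iloc[:0].copy(),
                              dosage=np.zeros((geno.n_samples, 0)))
    picked = np.sort(rng.choice(geno.n_sites, size=min(n_del, geno.n_sites),
                                replace=False))
    in_region = region_mask(geno.sites, cfg.regions)[picked]
    anc = truth.ancestry[:, picked].astype(int)
    q_mg = np.where(in_region, np.clip(base_rate * enrichment, 0, 1), base_rate)
    dose = np.zeros(anc.shape)
    for hap in range(2):
        has_mg = anc > hap  # this haplotype is wild-derived
        q = np.where(has_mg, q_mg[None, :], base_rate)
        dose += rng.random(anc.shape) < q
    sites = geno.sites.iloc[picked].reset_index(drop=True)
    sites["counted_allele"] = "alt"
    return GenotypeMatrix(samples=list(geno.samples), sites=sites, dosage=dose)


def apply_gbs_noise(
    geno: GenotypeMatrix, missing_rate: float = 0.0, jitter_sd: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Perturb dosages with imputation-style jitter and missingness.

    Dosages get additive Gaussian noise truncated to [0, 2], then a
    ``missing_rate`` fraction of calls is masked NaN. Reproducible from
    ``seed``; zero rates return an identical copy.
    """
    if not (0 <= missing_rate <= 1):
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
    d = geno.dosage.copy()
    if jitter_sd > 0:
        d = np.clip(d + rng.normal(0, jitter_sd, size=d.shape), 0.0, 2.0)
    if missing_rate > 0:
        d[rng.random(d.shape) < missing_rate] = np.nan
    return GenotypeMatrix(samples=list(geno.samples), sites=geno.sites.copy(), dosage=d)
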