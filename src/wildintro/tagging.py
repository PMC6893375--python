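"""LD-based reclassification of SNPs that tag the introgression partition.

Variance partitioning between introgressed and background kinships is only
meaningful if the two marker sets measure reasonably independent
relationships. Long-range LD lets background SNPs "tag" introgression
haplotypes; such SNPs are moved into the introgression partition when
their summed r-squared against the whole diagnostic-marker set (the
LD-score, ``totalLD``) exceeds a threshold chosen from a
kinship-correlation objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .kinship import make_grm, offdiag_correlation
from .ld import pairwise_r2


@dataclass
class GenomePartition:
    """Disjoint site-index sets whose union is every analyzed site."""

    idm: np.ndarray
    tag_idm: np.ndarray
    non_idm: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.idm = np.asarray(self.idm, dtype=int)
        self.tag_idm = np.asarray(self.tag_idm, dtype=int)
        self.non_idm = np.asarray(self.non_idm, dtype=int)
        all_idx = np.concatenate([self.idm, self.tag_idm, self.non_idm])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("partition sets overlap")

    @property
    def idm_plus_tag(self) -> np.ndarray:
        return np.sort(np.concatenate([self.idm, self.tag_idm]))


def compute_tag_stats(
    g: GenotypeMatrix, idm_sites, chunk: int = 512
) -> pd.DataFrame:
    """maxLD and totalLD of every non-IDM site against the full IDM set.

    maxLD is the largest squared dosage correlation with any IDM; totalLD
    is the sum over all IDMs (an LD-score against the diagnostic set).
    Undefined correlations (monomorphic columns) count as 0. Results are
    independent of ``chunk``, which only bounds memory.
    """
    idm_sites = np.asarray(sorted(idm_sites), dtype=int)
    if idm_sites.size == 0:
        raise ValueError("need at least one IDM site")
    non = np.setdiff1d(np.arange(g.n_sites), idm_sites)
    if non.size == 0:
        raise ValueError("need at least one non-IDM site")
    maxld = np.zeros(non.size)
    totld = np.zeros(non.size)
    for s in range(0, non.size, chunk):
        block = non[s : s + chunk]
        r2 = pairwise_r2(g, block, idm_sites)
        r2 = np.nan_to_num(r2, nan=0.0)
        maxld[s : s + len(block)] = r2.max(axis=1)
        totld[s : s + len(block)] = r2.sum(axis=1)
    return pd.DataFrame({"site_index": non, "maxLD": maxld, "totalLD": totld})


def apply_partition(
    tag_stats: pd.DataFrame,
    idm_sites,
    n_sites: int,
    ldscore_threshold: float = 500.0,
    maxld_threshold: float | None = None,
) -> GenomePartition:
    """Partition sites into idm / tag_idm / non_idm by LD-score threshold.

    A non-IDM site becomes tag-IDM when ``totalLD >= ldscore_threshold``
    and, if ``maxld_threshold`` is given, also ``maxLD >= maxld_threshold``
    (inclusive boundaries). The published analysis settled on the LD-score
    alone with threshold 500, which is the default here.
    """
    idm_sites = np.asarray(sorted(idm_sites), dtype=int)
    is_tag = tag_stats["totalLD"].to_numpy() >= ldscore_threshold
    if maxld_threshold is not None:
        is_tag &= tag_stats["maxLD"].to_numpy() >= maxld_threshold
    tag = tag_stats.loc[is_tag, "site_index"].to_numpy(dtype=int)
    non = tag_stats.loc[~is_tag, "site_index"].to_numpy(dtype=int)
    prov = f"ldscore>={ldscore_threshold}" + (
        f",maxld>={maxld_threshold}" if maxld_threshold is not None else ""
    )
    return GenomePartition(idm=idm_sites, tag_idm=np.sort(tag), non_idm=np.sort(non),
                           provenance=prov)


def evaluate_thresholds(
    g: GenotypeMatrix,
    idm_sites,
    tag_stats: pd.DataFrame | None = None,
    ldscore_grid=(300, 500, 700, 900, 1100, 1300, 1500),
    maxld_grid=(0.1, 0.3, 0.5, 0.7, 0.9, 1.0),
) -> pd.DataFrame:
    """Kinship-correlation objective over a grid of tagging thresholds.

    For each threshold (LD-score thresholds and maxLD thresholds are
    evaluated marginally, one statistic at a time) the genome is
    partitioned and four GRMs built: tag-IDM, IDM, non-IDM and
    IDM+tag-IDM. The off-diagonal correlations cor(tag, idm),
    cor(tag, non) and cor(idm+tag, non) are reported; the objective is to
    maximize the first while minimizing the other two. Rows with an empty
    tag set carry NaN correlations.
    """
    if tag_stats is None:
        tag_stats = compute_tag_stats(g, idm_sites)
    idm_sites = np.asarray(sorted(idm_sites), dtype=int)
    rows = []
    grid = [("ldscore", t, None) for t in ldscore_grid] + [
        ("maxld", None, t) for t in maxld_grid
    ]
    for kind, ls, ml in grid:
        if kind == "ldscore":
            part = apply_partition(tag_stats, idm_sites, g.n_sites, ldscore_threshold=ls)
        else:
            part = apply_partition(tag_stats, idm_sites, g.n_sites,
                                   ldscore_threshold=-np.inf, maxld_threshold=ml)
        n_tag = part.tag_idm.size
        if n_tag == 0 or part.non_idm.size < 2:
            rows.append((kind, ls, ml, n_tag, np.nan, np.nan, np.nan))
            continue
        k_idm = make_grm(g.take_sites(part.idm))
        k_non = make_grm(g.take_sites(part.non_idm))
        k_both = make_grm(g.take_sites(part.idm_plus_tag))
        try:
            k_tag = make_grm(g.take_sites(part.tag_idm))
            c_tag_idm = offdiag_correlation(k_tag, k_idm)
            c_tag_non = offdiag_correlation(k_tag, k_non)
        except ValueError:
            c_tag_idm = c_tag_non = np.nan
        c_both_non = offdiag_correlation(k_both, k_non)
        rows.append((kind, ls, ml, n_tag, c_tag_idm, c_tag_non, c_both_non))
    return pd.DataFrame(
        rows,
        columns=["statistic", "ldscore_threshold", "maxld_threshold", "n_tag",
                 "cor_tag_idm", "cor_tag_non", "cor_idmtag_non"],
    )


def random_partition(n_sites: int, n_idm_equivalent: int, seed: int) -> GenomePartition:
    """Uniform random site split of the same size as the diagnostic set.

    Used as a control: a random partition of equal marker count should
    explain variance roughly proportional to its size, unlike a partition
    that isolates true introgression signal.
    """
    if n_idm_equivalent > n_sites:
        raise ValueError("requested partition larger than site count")
    rng = np.random.default_rng(seed)
    picked = np.sort(rng.choice(n_sites, size=n_idm_equivalent, replace=False))
    rest = np.setdiff1d(np.arange(n_sites), picked)
    return GenomePartition(idm=picked, tag_idm=np.array([], dtype=int), non_idm=rest,
                           provenance=f"random(seed={seed})")
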