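"""Introgression diagnostic marker (IDM) detection.

The approach compares a wild-species reference panel (*M. glaziovii*-like,
"Mg") against per-window panels of non-introgressed cultivated samples
("Me"). A site is a *strict* IDM when the two panels are fixed for opposite
alleles, and a *glazpoly* IDM when the cultivated panel is fixed but the
wild panel segregates; the wild-diagnostic allele is the allele absent from
the cultivated panel. Me panels are chosen per window as the samples most
distant from the wild panel, so local introgressions cannot contaminate
the cultivated reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .ld import hamming_distance_matrix

log = logging.getLogger(__name__)


@dataclass
class WindowRefAssignment:
    """Per-window candidate distances and the selected cultivated panel."""

    window: int
    start: int  # site index span [start, stop), ordered by chrom,pos
    stop: int
    mean_glaz_dist: pd.Series  # per candidate sample id
    me_panel: list[str] = field(default_factory=list)
    kept: bool = True


def window_glaz_distance(
    g: GenotypeMatrix, mg_ids, window_size: int = 1000, min_tail: int = 100
) -> list[WindowRefAssignment]:
    """Mean Hamming distance of every non-wild sample to the wild panel,
    per nonoverlapping block of ``window_size`` sites.

    A terminal partial block of fewer than ``min_tail`` sites is merged
    into the preceding block.
    """
    mg_ids = list(mg_ids)
    if len(mg_ids) < 1:
        raise ValueError("need at least one wild-panel sample")
    order = np.lexsort((g.sites["pos"].to_numpy(), g.sites["chrom"].to_numpy().astype(str)))
    if not np.array_equal(order, np.arange(g.n_sites)):
        raise ValueError("sites must be ordered by chrom, pos")
    mg_idx = g.sample_index(mg_ids)
    cand_ids = [s for s in g.samples if s not in set(mg_ids)]
    cand_idx = g.sample_index(cand_ids)

    bounds = list(range(0, g.n_sites, window_size))
    stops = [min(b + window_size, g.n_sites) for b in bounds]
    if len(bounds) > 1 and stops[-1] - bounds[-1] < min_tail:
        bounds.pop()
        stops.pop()
        stops[-1] = g.n_sites

    out = []
    for w, (b, e) in enumerate(zip(bounds, stops)):
        D = hamming_distance_matrix(g.dosage[cand_idx, b:e], g.dosage[mg_idx, b:e])
        mean_d = pd.Series(D.mean(axis=1), index=cand_ids)
        out.append(WindowRefAssignment(window=w, start=b, stop=e, mean_glaz_dist=mean_d))
    return out


def select_me_reference(
    assignments: list[WindowRefAssignment], min_dist: float = 200.0, top_k: int = 10
) -> list[WindowRefAssignment]:
    """Choose each window's cultivated reference panel.

    Windows whose maximum distance from the wild panel is below
    ``min_dist`` are dropped (kept=False): these look wild-like everywhere
    and cannot anchor a cultivated reference. Otherwise the ``top_k``
    most-distant candidates form the panel; ties at the cutoff resolve to
    the lexicographically smaller sample id.
    """
    out = []
    for a in assignments:
        d = a.mean_glaz_dist
        if d.max() < min_dist:
            out.append(
                WindowRefAssignment(a.window, a.start, a.stop, d, me_panel=[], kept=False)
            )
            continue
        df = d.rename_axis("clone").reset_index(name="d")
        df = df.sort_values(["d", "clone"], ascending=[False, True])
        panel = df["clone"].head(top_k).tolist()
        if len(panel) < top_k:
            log.warning("window %d has only %d candidates (< top_k=%d)",
                        a.window, len(panel), top_k)
        out.append(WindowRefAssignment(a.window, a.start, a.stop, d, me_panel=panel, kept=True))
    return out


def _fixed_allele(hard: np.ndarray) -> str | None:
    """Return 'ref'/'alt' if all hard dosages are 0/2 respectively, else None.

    Any missing call disqualifies the site (returns 'missing').
    """
    if np.isnan(hard).any():
        return "missing"
    if (hard == 0).all():
        return "ref"
    if (hard == 2).all():
        return "alt"
    return None


def classify_idms(
    g: GenotypeMatrix, mg_ids, assignments: list[WindowRefAssignment]
) -> pd.DataFrame:
    """Classify diagnostic sites against each window's panels.

    Fixation is tested on hard (rounded) dosages with zero tolerance.
    Returns the IDM table with columns ``site_index, chrom, pos, id,
    idm_class ('strict'|'glazpoly'), mg_allele ('ref'|'alt'),
    me_fixed_allele``. Sites in dropped windows are never IDMs.
    """
    mg_idx = g.sample_index(list(mg_ids))
    hard = g.hard_dosage()
    rows = []
    for a in assignments:
        if not a.kept or not a.me_panel:
            continue
        me_idx = g.sample_index(a.me_panel)
        for j in range(a.start, a.stop):
            me = _fixed_allele(hard[me_idx, j])
            if me in (None, "missing"):
                continue
            mg_col = hard[mg_idx, j]
            if np.isnan(mg_col).any():
                continue
            mg_fixed = _fixed_allele(mg_col)
            other = "alt" if me == "ref" else "ref"
            if mg_fixed == other:
                cls = "strict"
            elif mg_fixed is None:
                # wild panel polymorphic: diagnostic only if it carries the
                # allele absent from the cultivated panel (it must, being
                # polymorphic at a biallelic site)
                cls = "glazpoly"
            else:
                continue  # both panels fixed for the same allele
            rows.append(
                (j, g.sites["chrom"].iloc[j], int(g.sites["pos"].iloc[j]),
                 g.sites["id"].iloc[j], cls, other, me)
            )
    return pd.DataFrame(
        rows,
        columns=["site_index", "chrom", "pos", "id", "idm_class", "mg_allele",
                 "me_fixed_allele"],
    )


def recode_to_mg_dosage(g: GenotypeMatrix, idm_table: pd.DataFrame) -> GenotypeMatrix:
    """Flip dosage counting at IDM sites so the counted allele is the
    wild-diagnostic allele.

    At IDM sites with ``mg_allele == 'ref'`` the dosage becomes
    ``2 - dosage`` and ``counted_allele`` is flipped; other sites are
    untouched. Applying the recode twice restores the original matrix.
    """
    dosage = g.dosage.copy()
    sites = g.sites.copy()
    flip = idm_table.loc[idm_table["mg_allele"] == "ref", "site_index"].to_numpy(dtype=int)
    dosage[:, flip] = 2.0 - dosage[:, flip]
    cur = sites["counted_allele"].to_numpy().copy()
    cur[flip] = np.where(cur[flip] == "alt", "ref", "alt")
    sites["counted_allele"] = cur
    return GenotypeMatrix(samples=list(g.samples), sites=sites, dosage=dosage)
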