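"""Genetic-map interpolation and recombination-density summaries."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GeneticMap, RegionSpec

log = logging.getLogger(__name__)


def interpolate_cM(gmap: GeneticMap, sites: pd.DataFrame) -> np.ndarray:
    """Linearly interpolate genetic position (cM) for sites with (chrom, pos).

    Sites outside the anchor span of their chromosome are clamped to the
    terminal anchor's cM. A chromosome absent from the map raises.
    """
    out = np.empty(len(sites))
    anchors = gmap.anchors
    have = set(anchors["chrom"].unique())
    want = set(sites["chrom"].unique())
    missing = sorted(str(c) for c in want - have)
    if missing:
        raise ValueError(f"chromosomes absent from genetic map: {missing}")
    for chrom, grp in sites.groupby("chrom", sort=False):
        a = anchors[anchors["chrom"] == chrom]
        if len(a) < 2:
            raise ValueError(f"need >=2 anchors on chromosome {chrom}")
        out[sites.index.get_indexer(grp.index)] = np.interp(
            grp["pos"].to_numpy(dtype=float),
            a["pos"].to_numpy(dtype=float),
            a["cM"].to_numpy(dtype=float),
        )
    return out


def recombination_density(
    gmap: GeneticMap,
    regions: list[RegionSpec],
    window: int = 1_000_000,
    chrom_lengths: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cumulative genetic size (cM) in fixed physical windows, and the
    percent reduction of recombination inside focal regions vs the rest
    of the genome.

    Returns ``(window_table, region_table)``. The window table has one row
    per (chrom, start, end) with its cM span; the region table reports the
    mean cM/Mb inside each region and ``100 * (1 - region / rest)``.
    """
    rows = []
    for chrom, a in gmap.anchors.groupby("chrom", sort=False):
        lo = 1
        hi = int(chrom_lengths[chrom]) if chrom_lengths else int(a["pos"].max())
        starts = np.arange(lo, hi, window)
        edges = np.append(starts, starts[-1] + window)
        sites = pd.DataFrame({"chrom": chrom, "pos": edges})
        cm = interpolate_cM(gmap, sites)
        for i, s in enumerate(starts):
            rows.append((chrom, int(s), int(s + window), cm[i + 1] - cm[i]))
    win = pd.DataFrame(rows, columns=["chrom", "start", "end", "cM"])

    mids = (win["start"] + win["end"] - 1) / 2.0
    in_any = np.zeros(len(win), dtype=bool)
    reg_rows = []
    for r in regions:
        inside = r.contains(win["chrom"].to_numpy(), mids.to_numpy())
        in_any |= inside
        reg_rows.append((r.label or f"{r.chrom}:{r.start}-{r.end}", inside))
    rest_rate = win.loc[~in_any, "cM"].mean() * (1_000_000 / window)
    out = []
    for label, inside in reg_rows:
        if not inside.any():
            log.warning("region %s covers no map windows; clamped to empty", label)
            out.append((label, np.nan, rest_rate, np.nan))
            continue
        rate = win.loc[inside, "cM"].mean() * (1_000_000 / window)
        reduction = 100.0 * (1.0 - rate / rest_rate) if rest_rate > 0 else np.nan
        out.append((label, rate, rest_rate, reduction))
    region_table = pd.DataFrame(
        out, columns=["region", "cM_per_Mb", "rest_cM_per_Mb", "pct_reduction"]
    )
    return win, region_table
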