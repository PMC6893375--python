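"""Core in-memory containers shared by every pipeline stage.

Genotypes are held as real-valued allelic dosages in [0, 2]: the count of
the "counted allele" per site, possibly fractional when dosages come from
imputation. Missing calls are NaN. Site metadata rides along in a pandas
DataFrame so positional subsetting keeps genotypes and annotation in sync.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "counted_allele"]


@dataclass
class GenotypeMatrix:
    """Sample x site dosage matrix with site metadata.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers (rows).
    sites : pandas.DataFrame
        One row per site with columns ``chrom, pos, id, ref, alt,
        counted_allele``; ``pos`` is 1-based. ``counted_allele`` is
        ``"alt"`` by default and may be flipped per site after recoding
        to the wild-diagnostic allele.
    dosage : ndarray, shape (n_samples, n_sites)
        Real dosages in [0, 2]; NaN marks missing calls.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2] (or be NaN)")
        if "counted_allele" not in self.sites.columns:
            self.sites = self.sites.assign(counted_allele="alt")
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos) in site table")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
        )

    def take_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites.copy(),
            dosage=self.dosage[idx, :],
        )

    def hard_dosage(self) -> np.ndarray:
        """Dosages rounded to the nearest integer (ties to even); NaN kept."""
        return np.round(self.dosage)


@dataclass
class GeneticMap:
    """Anchor markers tying physical (bp) to genetic (cM) position.

    ``anchors`` has columns ``chrom, pos, cM`` sorted by chrom then pos,
    with cM nondecreasing within each chromosome.
    """

    anchors: pd.DataFrame

    def __post_init__(self) -> None:
        a = self.anchors.sort_values(["chrom", "pos"]).reset_index(drop=True)
        for chrom, grp in a.groupby("chrom", sort=False):
            if (np.diff(grp["cM"].to_numpy()) < -1e-12).any():
                raise ValueError(f"cM not nondecreasing on {chrom}")
        self.anchors = a

    def chroms(self) -> list:
        return list(self.anchors["chrom"].unique())


@dataclass
class KinshipMatrix:
    """Square symmetric genomic relationship matrix over named samples."""

    samples: list[str]
    K: np.ndarray
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.samples)
        if self.K.shape != (n, n):
            raise ValueError("K dimension does not match samples")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K not symmetric within 1e-10")

    def align(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in kinship: {missing[:5]}")
        idx = np.array([lookup[s] for s in ids], dtype=int)
        return self.K[np.ix_(idx, idx)]


@dataclass
class RegionSpec:
    """Half-open genomic interval [start, end) in bp, 1-based start."""

    chrom: object
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("region start must be < end")

    def contains(self, chrom, pos) -> np.ndarray:
        pos = np.asarray(pos)
        return (np.asarray(chrom) == self.chrom) & (pos >= self.start) & (pos < self.end)


def region_mask(sites: pd.DataFrame, regions) -> np.ndarray:
    """Boolean mask of sites falling in any of ``regions`` (half-open bp)."""
    mask = np.zeros(len(sites), dtype=bool)
    for r in regions:
        mask |= r.contains(sites["chrom"].to_numpy(), sites["pos"].to_numpy())
    return mask


@dataclass
class DoseGlazMatrix:
    """Per-sample mean wild-diagnostic dosage in nonoverlapping windows.

    ``windows`` has columns ``chrom, start, end, n_idm`` (half-open bp);
    ``values`` is samples x windows with NaN where a window holds no
    diagnostic markers.
    """

    samples: list[str]
    windows: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.windows)):
            raise ValueError("values shape mismatch")


# Phenotype records are a plain pandas DataFrame with one row per plot
# observation and columns: clone, trait, value, trial, loc_year, rep,
# block, nohav (nohav may be NaN for non-yield traits).
PHENOTYPE_COLUMNS = ["clone", "trait", "value", "trial", "loc_year", "rep", "block", "nohav"]


def check_phenotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype-record table, filling optional columns with NaN."""
    rec = records.copy()
    for col in PHENOTYPE_COLUMNS:
        if col not in rec.columns:
            if col in ("value", "clone", "trait"):
                raise ValueError(f"phenotype records missing column {col!r}")
            rec[col] = np.nan
    if (rec["nohav"].dropna() < 0).any():
        raise ValueError("NOHAV must be nonnegative")
    return rec[PHENOTYPE_COLUMNS + [c for c in rec.columns if c not in PHENOTYPE_COLUMNS]]
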