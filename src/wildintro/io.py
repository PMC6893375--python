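"""Readers and writers for the plain-text formats the pipeline exchanges.

Supported inputs: VCF 4.x (GT or DS per sample; biallelic sites only),
dosage TSV (samples as rows, header row of site ids), genetic-map TSV
(chrom, pos, cM) and phenotype TSV. GRMs are written as TSV with a
sample-id sidecar.
"""

from __future__ import annotations

import logging
import os
import re

import numpy as np
import pandas as pd

from .containers import GeneticMap, GenotypeMatrix, KinshipMatrix, check_phenotypes

log = logging.getLogger(__name__)


def read_genotypes(path: str, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype dosage matrix from VCF or dosage TSV.

    For VCF, per-sample dosage is the DS field when present, otherwise the
    count of ALT alleles in GT. Multiallelic records are skipped with a
    warning. Site order is preserved.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            log.warning("skipping multiallelic site %s:%s", var.CHROM, var.POS)
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = var.gt_types.astype(float)
            dose = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        rows.append(
            (var.CHROM, var.POS, var.ID or f"{var.CHROM}_{var.POS}", var.REF, var.ALT[0])
        )
        cols.append(dose)
    if not cols:
        raise ValueError(f"no usable biallelic records in {path}")
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    sites["counted_allele"] = "alt"
    return GenotypeMatrix(samples=samples, sites=sites, dosage=np.column_stack(cols))


_SITE_ID = re.compile(r"^(?P<chrom>[^_]+)_(?P<pos>\d+)$")


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = [str(s) for s in df.index]
    ids = [str(c) for c in df.columns]
    chroms, poss = [], []
    for i, sid in enumerate(ids):
        m = _SITE_ID.match(sid)
        if m:
            chroms.append(m.group("chrom"))
            poss.append(int(m.group("pos")))
        else:
            chroms.append("0")
            poss.append(i + 1)
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "id": ids, "ref": "A", "alt": "B",
         "counted_allele": "alt"}
    )
    return GenotypeMatrix(samples=samples, sites=sites, dosage=df.to_numpy(dtype=float))


def write_dosage_tsv(g: GenotypeMatrix, path: str) -> None:
    pd.DataFrame(g.dosage, index=g.samples, columns=g.sites["id"]).to_csv(path, sep="\t")


def read_genetic_map(path: str) -> GeneticMap:
    """Read an anchor-marker map TSV with columns chrom, pos, cM."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    try:
        df = df.rename(columns={cols["chrom"]: "chrom", cols["pos"]: "pos", cols["cm"]: "cM"})
    except KeyError as exc:
        raise ValueError(f"map file must have chrom/pos/cM columns, got {list(df.columns)}") from exc
    return GeneticMap(anchors=df[["chrom", "pos", "cM"]])


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read plot-level phenotype records (clone, trait, value, trial, ...)."""
    return check_phenotypes(pd.read_csv(path, sep="\t"))


def write_grm(k: KinshipMatrix, path: str) -> None:
    """Write a GRM as TSV plus a `<path>.ids` sample-id sidecar."""
    np.savetxt(path, k.K, delimiter="\t")
    with open(path + ".ids", "w") as fh:
        fh.write("\n".join(k.samples) + "\n")


def read_grm(path: str, method_tag: str = "") -> KinshipMatrix:
    K = np.loadtxt(path, delimiter="\t")
    with open(path + ".ids") as fh:
        samples = [line.strip() for line in fh if line.strip()]
    return KinshipMatrix(samples=samples, K=K, method_tag=method_tag)


def write_doseglaz_tsv(dose, path: str) -> None:
    """Window-dosage matrix as TSV: samples x windows (chrom:start-end ids)."""
    cols = [
        f"{c}:{s}-{e}"
        for c, s, e in zip(dose.windows["chrom"], dose.windows["start"],
                           dose.windows["end"])
    ]
    pd.DataFrame(dose.values, index=dose.samples, columns=cols).to_csv(path, sep="\t")


def write_doseglaz_bedgraph(dose, sample: str, path: str) -> None:
    """One sample's window dosages as a bedGraph-style track
    (chrom, 0-based start, end, value); empty windows are skipped."""
    i = dose.samples.index(sample)
    with open(path, "w") as fh:
        for j in range(len(dose.windows)):
            v = dose.values[i, j]
            if not np.isfinite(v):
                continue
            w = dose.windows.iloc[j]
            fh.write(f"{w['chrom']}\t{int(w['start']) - 1}\t{int(w['end']) - 1}\t{v:.6g}\n")
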