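"""Readers and writers for the plain-text interchange formats.

Expression comes as one tab-delimited matrix per tissue (rows = genes,
columns = subjects, "NA" for missing), genotypes as a tab-delimited dosage
matrix (first three columns snp_id, chrom, pos; remaining columns subject
dosages 0/1/2 or NA) or a VCF, and gene annotations as a BED-like table
(chrom, tss, gene_id, strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionBlock, GenotypeVector

__all__ = [
    "GenotypeMatrix",
    "read_expression_table",
    "read_expression_tables",
    "assemble_block",
    "read_genotype_matrix",
    "read_genotypes_vcf",
    "read_annotations",
    "read_scan_config",
]


@dataclass
class GenotypeMatrix:
    """SNPs x subjects dosage matrix plus SNP metadata."""

    meta: pd.DataFrame  # columns snp_id, chrom, pos
    dosages: np.ndarray  # (m, n) float, NaN for missing
    subject_ids: list

    def __post_init__(self):
        self.meta = self.meta.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.subject_ids = list(self.subject_ids)
        if self.dosages.shape != (len(self.meta), len(self.subject_ids)):
            raise ValueError("dosage matrix shape does not match metadata")

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    def vector(self, j: int) -> GenotypeVector:
        row = self.meta.iloc[j]
        return GenotypeVector(
            dosages=self.dosages[j],
            snp_id=str(row["snp_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
        )


def read_expression_table(path) -> pd.DataFrame:
    """One tissue's genes x subjects table; 'NA' parsed as missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.columns = [str(c) for c in df.columns]
    return df


def read_expression_tables(paths: Mapping[str, "str | Path"]) -> dict:
    """Mapping tissue id -> path, read into tissue id -> DataFrame."""
    return {tissue: read_expression_table(p) for tissue, p in paths.items()}


def assemble_block(
    gene_id: str,
    tissue_tables: Mapping[str, pd.DataFrame],
    subject_ids: Sequence[str],
) -> ExpressionBlock:
    """Collect one gene's subjects x tissues block from per-tissue tables.

    A subject-tissue cell is missing when the subject is absent from that
    tissue's table, the gene is absent, or the stored value is NA.
    """
    tissues = list(tissue_tables)
    n, t = len(subject_ids), len(tissues)
    values = np.full((n, t), np.nan)
    for j, tissue in enumerate(tissues):
        df = tissue_tables[tissue]
        if gene_id not in df.index:
            continue
        row = df.loc[gene_id]
        present = [s for s in subject_ids if s in row.index]
        idx = [subject_ids.index(s) for s in present]
        values[idx, j] = row[present].to_numpy(dtype=float)
    return ExpressionBlock(
        values=values, subject_ids=list(subject_ids), tissue_ids=tissues
    )


def read_genotype_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = ["snp_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"genotype table must start with columns {required}")
    subjects = [str(c) for c in df.columns[3:]]
    meta = df[required].copy()
    meta["chrom"] = meta["chrom"].astype(str)
    dosages = df.iloc[:, 3:].to_numpy(dtype=float)
    return GenotypeMatrix(meta=meta, dosages=dosages, subject_ids=subjects)


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read GT fields of a VCF into ALT-allele dosages (0/1/2, NaN unknown)."""
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path), gts012=True)
    subjects = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan  # 3 encodes unknown under gts012
        rows.append(gt)
        meta.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
            }
        )
    return GenotypeMatrix(
        meta=pd.DataFrame(meta, columns=["snp_id", "chrom", "pos"]),
        dosages=np.vstack(rows) if rows else np.empty((0, len(subjects))),
        subject_ids=subjects,
    )


def read_annotations(path) -> pd.DataFrame:
    """BED-like gene annotation: chrom, tss, gene_id, strand (tab-delimited)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "tss", "gene_id", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    df["tss"] = df["tss"].astype(int)
    if (df["tss"] < 1).any():
        raise ValueError("tss coordinates are 1-based and must be >= 1")
    return df


def read_scan_config(path) -> dict:
    """YAML key-value scan configuration (window, alpha, permutations, ...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("scan config must be a key-value mapping")
    return cfg
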