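"""End-to-end cis and genome-wide eQTL scans.

The scan walks genes, fits each gene's null model exactly once, tests every
paired SNP with the joint score test, and applies the requested multiplicity
control: a Bonferroni flag on pair p-values (denominator #genes x #SNPs for
genome-wide scans, #pairs for cis scans) and, when permutations are
requested, a gene-level permutation min-p table with Benjamini-Hochberg
adjusted values.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionBlock
from .errors import CollinearCovariatesError, DegenerateDataError, SubjectMismatchError
from .io import GenotypeMatrix, assemble_block
from .model import fit_null
from .multiplicity import bh_fdr, bonferroni_threshold, permute_gene
from .score import joint_test

__all__ = [
    "GeneAnnotation",
    "ScanConfig",
    "ScanResult",
    "residualize",
    "cis_pairs",
    "run_scan",
    "winsorized_mean",
]

logger = logging.getLogger("tissueqtl.scan")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int  # 1-based transcription start position
    strand: str = "+"

    def __post_init__(self):
        if self.tss < 1:
            raise ValueError("tss must be >= 1 (1-based)")


@dataclass
class ScanConfig:
    mode: str = "cis"  # "cis" | "genomewide"
    window: int = 100_000
    alpha: float = 0.05
    permutations: int = 0
    seed: int = 0
    covariates: Optional[pd.DataFrame] = None  # subjects x covariates

    def __post_init__(self):
        if self.mode not in ("cis", "genomewide"):
            raise ValueError("mode must be 'cis' or 'genomewide'")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ScanResult:
    pairs: pd.DataFrame
    genes: Optional[pd.DataFrame]
    threshold: float
    n_tested: int


def residualize(expr: ExpressionBlock, covariates: pd.DataFrame) -> ExpressionBlock:
    """Replace each tissue's values by OLS residuals on the covariates.

    An intercept is always included, so intercept-only covariates reduce to
    per-tissue mean centering.  The missingness mask is preserved.  Raises
    :class:`CollinearCovariatesError` naming the offending columns when the
    design (with intercept) is rank deficient.
    """
    cov = covariates.reindex(expr.subject_ids)
    if cov.isna().any().any():
        missing = cov.index[cov.isna().any(axis=1)].tolist()
        raise ValueError(f"covariates missing for subjects: {missing}")
    X = np.column_stack([np.ones(expr.n_subjects), cov.to_numpy(dtype=float)])
    names = ["intercept"] + [str(c) for c in cov.columns]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        kept = [0]
        for j in range(1, X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                collinear.append(names[j])
        raise CollinearCovariatesError(
            f"covariate design is rank deficient; collinear columns: {collinear}"
        )
    out = np.full_like(expr.values, np.nan)
    for j in range(expr.n_tissues):
        rows = expr.mask[:, j]
        if rows.sum() <= X.shape[1]:
            out[rows, j] = 0.0
            continue
        y = expr.values[rows, j]
        coef, *_ = np.linalg.lstsq(X[rows], y, rcond=None)
        out[rows, j] = y - X[rows] @ coef
    return ExpressionBlock(
        values=out, mask=expr.mask, subject_ids=expr.subject_ids,
        tissue_ids=expr.tissue_ids,
    )


def cis_pairs(
    genes: Sequence[GeneAnnotation],
    snp_meta: pd.DataFrame,
    window: int = 100_000,
) -> dict:
    """Map gene_id -> indices of SNPs with |pos - tss| <= window on the same chromosome.

    The boundary is inclusive at exactly +/- window; strand is ignored for
    the distance.  Genes with no cis SNP map to an empty index array.
    """
    out = {}
    chrom = snp_meta["chrom"].astype(str).to_numpy()
    pos = snp_meta["pos"].to_numpy()
    by_chrom = {}
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        order = np.argsort(pos[idx], kind="stable")
        by_chrom[c] = (idx[order], pos[idx][order])
    for gene in genes:
        idx_sorted, pos_sorted = by_chrom.get(str(gene.chrom), (np.array([], int), np.array([], int)))
        lo = np.searchsorted(pos_sorted, gene.tss - window, side="left")
        hi = np.searchsorted(pos_sorted, gene.tss + window, side="right")
        out[gene.gene_id] = np.sort(idx_sorted[lo:hi])
    return out


def _check_subjects(expr_subjects, geno_subjects):
    se, sg = set(expr_subjects), set(geno_subjects)
    if se != sg:
        only_expr = sorted(se - sg)
        only_geno = sorted(sg - se)
        raise SubjectMismatchError(
            "expression/genotype subject mismatch; "
            f"only in expression: {only_expr}; only in genotypes: {only_geno}"
        )


def run_scan(
    tissue_tables: Mapping[str, pd.DataFrame],
    genotypes: GenotypeMatrix,
    annotations: Optional[Sequence[GeneAnnotation]],
    config: ScanConfig,
) -> ScanResult:
    """Scan all genes against their paired SNPs with the joint score test.

    cis mode pairs each annotated gene with SNPs within ``window`` of its
    TSS; genome-wide mode tests every gene against every SNP.  Each gene's
    null model is fitted once and reused for all of its SNPs.  Returns the
    per-pair results plus, when ``config.permutations > 0``, a per-gene
    permutation table with BH-adjusted p-values.
    """
    expr_subjects = set()
    for df in tissue_tables.values():
        expr_subjects |= set(map(str, df.columns))
    _check_subjects(expr_subjects, genotypes.subject_ids)
    subjects = list(genotypes.subject_ids)

    gene_universe = sorted(set().union(*[set(df.index) for df in tissue_tables.values()]))
    if config.mode == "cis":
        if annotations is None:
            raise ValueError("cis mode requires gene annotations")
        genes = [a for a in annotations if a.gene_id in set(gene_universe)]
        pairing = cis_pairs(genes, genotypes.meta, config.window)
        gene_ids = [a.gene_id for a in genes]
        n_pairs_total = int(sum(len(v) for v in pairing.values()))
        threshold = (
            bonferroni_threshold(config.alpha, [n_pairs_total]) if n_pairs_total else np.nan
        )
    else:
        gene_ids = gene_universe
        all_idx = np.arange(genotypes.n_snps)
        pairing = {g: all_idx for g in gene_ids}
        n_pairs_total = len(gene_ids) * genotypes.n_snps
        threshold = bonferroni_threshold(config.alpha, [len(gene_ids), genotypes.n_snps])

    rows = []
    gene_rows = []
    for gi, gene_id in enumerate(gene_ids):
        snp_idx = pairing[gene_id]
        block = assemble_block(gene_id, tissue_tables, subjects)
        if config.covariates is not None:
            block = residualize(block, config.covariates)
        try:
            fit = fit_null(block)
        except DegenerateDataError as e:
            logger.warning("gene %s skipped: %s", gene_id, e)
            continue
        logger.info(
            "gene %s: null fit in %d iterations, %d SNPs", gene_id, fit.n_iter, len(snp_idx)
        )
        gene_vectors = []
        for j in snp_idx:
            g = genotypes.vector(int(j))
            res = joint_test(fit, g)
            rows.append(
                {
                    "gene_id": gene_id,
                    "snp_id": g.snp_id,
                    "u_beta": res.u_beta,
                    "u_gamma": res.u_gamma,
                    "u_psi": res.u_psi,
                    "nu": res.nu,
                    "kappa": res.kappa,
                    "p_value": res.p_value,
                    "flag": res.flag,
                    "significant": bool(res.p_value < threshold) if not res.flag else False,
                }
            )
            gene_vectors.append(g)
        if config.permutations > 0 and gene_vectors:
            pr = permute_gene(
                fit,
                gene_vectors,
                B=config.permutations,
                seed=(int(config.seed) + gi) % (2**31),
                gene_id=gene_id,
            )
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "observed_min_p": pr.observed_min_p,
                    "adjusted_p": pr.adjusted_p,
                    "B": pr.n_permutations,
                    "seed": pr.rng_seed,
                    "flag": pr.flag,
                }
            )

    pair_df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "snp_id", "u_beta", "u_gamma", "u_psi",
            "nu", "kappa", "p_value", "flag", "significant",
        ],
    )
    genes_df = None
    if gene_rows:
        genes_df = pd.DataFrame(gene_rows)
        ok = genes_df["flag"] == ""
        adj = np.full(len(genes_df), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = bh_fdr(genes_df.loc[ok, "adjusted_p"].to_numpy())
        genes_df["bh_adjusted_p"] = adj
    return ScanResult(
        pairs=pair_df, genes=genes_df, threshold=float(threshold), n_tested=len(pair_df)
    )


def winsorized_mean(values, fraction: float = 0.1) -> float:
    """Mean after clamping the lowest/highest floor(fraction*n) values.

    The extreme order statistics are replaced by the nearest retained ones
    (symmetric winsorisation); fraction = 0 gives the arithmetic mean.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("winsorized_mean of empty input")
    if not (0.0 <= fraction < 0.5):
        raise ValueError("fraction must lie in [0, 0.5)")
    k = int(np.floor(fraction * v.size))
    if k == 0:
        return float(v.mean())
    s = np.sort(v)
    s[:k] = s[k]
    s[-k:] = s[-k - 1]
    return float(s.mean())
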