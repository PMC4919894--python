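"""Gene-level permutation adjustment and multiple-testing control.

A gene's evidence is summarised by the minimum joint-test p-value over its
candidate SNPs.  Because cis SNPs are in LD and share one expression
phenotype, that minimum has no simple null distribution; it is calibrated by
permuting the *genotype* subject labels — one shared permutation per
iteration across all SNPs, which preserves both the cross-tissue expression
correlation and the LD structure — and recomputing the min-p against the
unpermuted null fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeVector
from .model import NullFit
from .score import joint_test

__all__ = [
    "GenePermutationResult",
    "permute_gene",
    "bh_fdr",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class GenePermutationResult:
    gene_id: str
    observed_min_p: float
    n_permutations: int
    adjusted_p: float
    rng_seed: int
    flag: str = ""


def _min_p(fit: NullFit, dosage_rows, weight_rule: str) -> float:
    best = np.inf
    for d in dosage_rows:
        res = joint_test(fit, d, weight_rule=weight_rule)
        if not res.flag and res.p_value < best:
            best = res.p_value
    return best


def permute_gene(
    fit: NullFit,
    genotypes: Sequence[GenotypeVector],
    B: int,
    seed: int,
    gene_id: str = "gene",
    add_one: bool = True,
    weight_rule: str = "inv_sd",
) -> GenePermutationResult:
    """Permutation min-p adjusted p-value for one gene.

    ``adjusted_p`` is the fraction of permutations whose min-p is at most the
    observed min-p; with ``add_one`` (default) the conservative add-one rule
    ``(1 + k) / (B + 1)`` is used so the result is never zero.

    Parameters
    ----------
    fit : NullFit
        The gene's null fit (never refitted during permutation).
    genotypes : sequence of GenotypeVector (or dosage arrays)
        Candidate SNPs; degenerate SNPs are ignored.
    B : int
        Number of permutations (>= 1).
    seed : int
        Seed of the permutation stream; same seed, same result, bit for bit.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rows = [
        g.dosages if isinstance(g, GenotypeVector) else np.asarray(g, dtype=float)
        for g in genotypes
    ]
    obs = _min_p(fit, rows, weight_rule)
    if not np.isfinite(obs):  # every SNP degenerate
        return GenePermutationResult(gene_id, np.nan, B, 1.0, seed, flag="all_degenerate")

    rng = np.random.default_rng(seed)
    n = fit.n_subjects
    D = np.vstack(rows)
    k = 0
    for _ in range(B):
        perm = rng.permutation(n)
        if _min_p(fit, D[:, perm], weight_rule) <= obs:
            k += 1
    adj = (1.0 + k) / (B + 1.0) if add_one else k / B
    return GenePermutationResult(gene_id, float(obs), B, float(adj), seed)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(alpha: float, counts) -> float:
    """Family-wise threshold alpha / prod(counts).

    ``counts`` lists the multiplicity factors, e.g. (tissues, cis pairs) for
    a tissue-by-tissue cis scan or (genes, SNPs) for a genome-wide joint scan.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    counts = list(counts)
    if not counts:
        raise ValueError("counts must be non-empty")
    if any(int(c) != c or c < 1 for c in counts):
        raise ValueError("counts must be positive integers")
    return float(alpha) / float(np.prod([float(c) for c in counts]))
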