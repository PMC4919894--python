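"""Synthetic multi-tissue eQTL data and the type-I error / power experiments.

One simulated dataset is a single gene-SNP pair: genotypes are drawn under
Hardy-Weinberg equilibrium at a given minor allele frequency, then expression
follows the generative model

    y_is = alpha_s + beta*g_i + u_i + g_i*v_s + e_is,

with subject intercepts u_i ~ N(0, tau), a tissue-specific genotype effect
v_s ~ N(0, gamma) drawn once per gene (shared by all subjects), and noise
e_is ~ N(0, eps).  The interaction strength is parameterised by
PVE_gamma = gamma / (tau + gamma + eps); by default the total variance
tau + gamma + eps is normalised to 1 with tau = eps = (1 - gamma)/2, so a
beta of 0.5 is a half-standard-deviation additive effect.

The tissue-by-tissue (TBT) baseline regresses expression on dosage
separately in each tissue and takes the minimum two-sided slope p-value,
assessed at alpha / t.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionBlock, GenotypeVector
from .model import fit_null
from .score import joint_test

__all__ = [
    "SimulationConfig",
    "genotypes_hwe",
    "simulate_gene",
    "tbt_test",
    "type_I_error",
    "power_grid",
    "benchmark_panel",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of one simulation cell.

    ``tau`` and ``epsilon`` may be left None, in which case the total
    variance is normalised to 1: gamma = pve_gamma, tau = epsilon =
    (1 - gamma)/2.  If given explicitly, gamma is derived from
    pve_gamma = gamma / (tau + gamma + epsilon).
    """

    n: int = 100
    t: int = 5
    maf: float = 0.05
    beta: float = 0.0
    pve_gamma: float = 0.0
    tau: Optional[float] = None
    epsilon: Optional[float] = None
    alpha: Optional[Sequence[float]] = None  # tissue intercepts, default 0
    missing_rate: float = 0.0
    replicates: int = 5000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if not (0.0 <= self.pve_gamma < 1.0):
            raise ValueError("pve_gamma must lie in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if (self.tau is None) != (self.epsilon is None):
            raise ValueError("give both tau and epsilon or neither")

    def variance_components(self):
        """Resolved (tau, gamma, epsilon)."""
        if self.tau is None:
            gamma = self.pve_gamma
            tau = eps = (1.0 - gamma) / 2.0
        else:
            tau, eps = float(self.tau), float(self.epsilon)
            gamma = self.pve_gamma * (tau + eps) / (1.0 - self.pve_gamma)
        if eps <= 0:
            raise ValueError("epsilon must resolve to a positive value")
        return tau, gamma, eps

    def intercepts(self) -> np.ndarray:
        if self.alpha is None:
            return np.zeros(self.t)
        a = np.asarray(self.alpha, dtype=float)
        if a.size != self.t:
            raise ValueError("alpha must have length t")
        return a


def genotypes_hwe(n: int, maf: float, rng: np.random.Generator, **meta) -> GenotypeVector:
    """n i.i.d. dosages with Hardy-Weinberg frequencies ((1-p)^2, 2p(1-p), p^2)."""
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    p = maf
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
    d = rng.choice([0.0, 1.0, 2.0], size=n, p=probs)
    meta.setdefault("snp_id", "sim_snp")
    return GenotypeVector(dosages=d, **meta)


def simulate_gene(
    config: SimulationConfig, g: GenotypeVector, rng: np.random.Generator
) -> ExpressionBlock:
    """One gene's expression block under the generative model given genotypes.

    ``v`` is drawn once per gene and shared by all subjects, matching a
    random tissue-by-genotype effect with covariance gamma * XX'.
    """
    tau, gamma, eps = config.variance_components()
    n, t = config.n, config.t
    d = g.dosages
    if d.size != n:
        raise ValueError("genotype length must equal config.n")
    alpha = config.intercepts()
    u = rng.normal(0.0, np.sqrt(tau), size=n)
    v = rng.normal(0.0, np.sqrt(gamma), size=t) if gamma > 0 else np.zeros(t)
    e = rng.normal(0.0, np.sqrt(eps), size=(n, t))
    y = alpha + config.beta * d[:, None] + u[:, None] + d[:, None] * v + e
    mask = None
    if config.missing_rate > 0:
        mask = rng.random((n, t)) >= config.missing_rate
    return ExpressionBlock(values=y, mask=mask)


def tbt_test(expr: ExpressionBlock, g: GenotypeVector):
    """Tissue-by-tissue baseline: per-tissue OLS slope test, minimum p.

    Returns (p-values per tissue, min_p).  Tissues with a degenerate design
    (constant dosage among its observed subjects, or fewer than 3 complete
    pairs) get p = 1.
    """
    d = g.dosages if isinstance(g, GenotypeVector) else np.asarray(g, dtype=float)
    y = expr.values
    obs = expr.mask & np.isfinite(d)[:, None]
    m = obs.sum(axis=0).astype(float)

    d0 = np.where(obs, d[:, None], 0.0)
    y0 = np.where(obs, y, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dbar = d0.sum(axis=0) / m
        ybar = y0.sum(axis=0) / m
        sxx = ((d0 - dbar) ** 2 * obs).sum(axis=0)
        sxy = ((d0 - dbar) * (y0 - ybar) * obs).sum(axis=0)
        syy = ((y0 - ybar) ** 2 * obs).sum(axis=0)
        slope = sxy / sxx
        rss = syy - slope * sxy
        df = m - 2.0
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
        tval = slope / se
        p = 2.0 * stats.t.sf(np.abs(tval), df)
        # exact fits: rss ~ 0 -> se 0 -> |t| = inf -> p = 0; keep that
        p = np.where(np.isnan(tval) & (sxx > 0) & (df > 0), 0.0, p)
    bad = (m < 3) | (sxx <= 0)
    p = np.where(bad, 1.0, p)
    return p, float(p.min())


def _rep_rng(base_seed: int, rep: int) -> np.random.Generator:
    # one stream per replicate: reproducible and order independent
    return np.random.default_rng((int(base_seed) % (2**31), rep))


def _one_replicate(config: SimulationConfig, rep: int):
    rng = _rep_rng(config.seed, rep)
    g = genotypes_hwe(config.n, config.maf, rng)
    expr = simulate_gene(config, g, rng)
    return expr, g


def type_I_error(
    config: SimulationConfig,
    method: str = "joint",
    alpha: float = 0.05,
) -> float:
    """Empirical rejection rate under the null (requires beta = 0, pve_gamma = 0).

    The joint test rejects at p < alpha; TBT rejects when its min-p beats the
    per-tissue Bonferroni level alpha / t.  Degenerate replicates (monomorphic
    draws) count as non-rejections.
    """
    if config.beta != 0.0 or config.pve_gamma != 0.0:
        raise ValueError("type_I_error requires a null config (beta = 0, pve_gamma = 0)")
    return _rejection_rate(config, method, alpha)


def _rejection_rate(config: SimulationConfig, method: str, alpha: float) -> float:
    if method not in ("joint", "tbt"):
        raise ValueError("method must be 'joint' or 'tbt'")
    hits = 0
    for rep in range(config.replicates):
        expr, g = _one_replicate(config, rep)
        if method == "joint":
            if g.is_degenerate():
                continue
            fit = fit_null(expr)
            hits += joint_test(fit, g).p_value < alpha
        else:
            _, min_p = tbt_test(expr, g)
            hits += min_p < alpha / config.t
    return hits / config.replicates


def power_grid(
    base: SimulationConfig,
    betas: Sequence[float] = (0.0, 0.5),
    pves: Sequence[float] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25),
    methods: Sequence[str] = ("joint", "tbt"),
    alpha: float = 0.05,
    replicates: int = 1000,
) -> pd.DataFrame:
    """Rejection rates over the (beta, PVE_gamma) grid for each method.

    Returns a tidy frame with columns beta, pve_gamma, method, power,
    replicates.  The (0, 0) corner is the type-I error of each method.
    """
    rows = []
    for b in betas:
        for pv in pves:
            cfg = replace(base, beta=float(b), pve_gamma=float(pv), replicates=replicates)
            for method in methods:
                rate = _rejection_rate(cfg, method, alpha)
                rows.append(
                    {
                        "beta": float(b),
                        "pve_gamma": float(pv),
                        "method": method,
                        "power": rate,
                        "replicates": replicates,
                    }
                )
    return pd.DataFrame(rows)


def benchmark_panel(
    n_genes: int = 100,
    n_snps: int = 1036,
    n: int = 100,
    t: int = 5,
    maf: float = 0.30,
    frac_null: float = 0.5,
    beta_alt: float = 0.5,
    pve_alt: float = 0.10,
    seed: int = 0,
):
    """Speed-benchmark style panel: a gene x SNP grid with half null genes.

    Returns (expression blocks by gene id, genotype matrix rows, cis map of
    gene id -> SNP indices).  Intended for timing and end-to-end smoke runs,
    not for calibrated power statements.
    """
    rng = np.random.default_rng(seed)
    snps = [
        genotypes_hwe(n, maf, rng, snp_id=f"snp{j}", chrom="1", pos=1000 * (j + 1))
        for j in range(n_snps)
    ]
    blocks = {}
    cis = {}
    per_gene = max(n_snps // n_genes, 1)
    for i in range(n_genes):
        idx = np.arange(i * per_gene, min((i + 1) * per_gene, n_snps))
        if idx.size == 0:
            idx = np.array([n_snps - 1])
        null_gene = i < int(frac_null * n_genes)
        cfg = SimulationConfig(
            n=n, t=t, maf=maf,
            beta=0.0 if null_gene else beta_alt,
            pve_gamma=0.0 if null_gene else pve_alt,
            seed=seed,
        )
        blocks[f"gene{i}"] = simulate_gene(cfg, snps[idx[0]], rng)
        cis[f"gene{i}"] = idx
    return blocks, snps, cis
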