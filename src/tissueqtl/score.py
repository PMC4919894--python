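"""Joint score test for a shared and a tissue-specific genotype effect.

Under the alternative the model adds a fixed cross-tissue genotype effect
``beta`` and a tissue-by-genotype random effect with variance ``gamma``:

    Y = J*alpha + G*beta + Z*u + X*v + xi,
    u ~ N(0, tau*ZZ'), v ~ N(0, gamma*XX'), xi ~ N(0, eps*I),

with ``G`` the stacked dosages and ``X`` the nt x t design whose subject-i
block is ``g_i * I_t`` (restricted to observed tissues).  The efficient
scores at the null (beta = gamma = 0) are

    U_beta  = (G - Gbar)' Sigma^-1 (Y - J alpha_hat)
    U_gamma = 1/2 (Y - J alpha_hat)' Sigma^-1 X X' Sigma^-1 (Y - J alpha_hat)

and the joint statistic is the weighted sum U_psi = a_beta*U_beta^2 +
a_gamma*U_gamma, calibrated against a Satterthwaite scaled chi-square whose
first two moments match the exact null moments of U_psi.  The moments use
the alpha-projected residual covariance V = Sigma - J (J'Sigma^-1 J)^-1 J',
which accounts for intercept estimation and is what keeps the small-sample
type-I error at its nominal level.

All quantities are computed through the per-subject Woodbury blocks cached
on the :class:`~tissueqtl.model.NullFit`; no nt x nt matrix is ever formed,
so one SNP costs O(n*t) after the (per-gene) null fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .containers import GenotypeVector
from .model import NullFit

__all__ = [
    "ScoreMoments",
    "JointScoreResult",
    "score_beta",
    "score_gamma",
    "null_moments",
    "combine",
    "satterthwaite_p",
    "joint_test",
]

_P_FLOOR = np.nextafter(0.0, 1.0)

GenotypeLike = Union[GenotypeVector, np.ndarray]


def _dosages(g: GenotypeLike) -> np.ndarray:
    if isinstance(g, GenotypeVector):
        return g.dosages
    return np.asarray(g, dtype=float).ravel()


def _retained(fit: NullFit, d: np.ndarray) -> np.ndarray:
    """Subjects entering this SNP's test: observed dosage and >=1 tissue."""
    if d.size != fit.n_subjects:
        raise ValueError("genotype and fit refer to different numbers of subjects")
    return np.isfinite(d) & (fit.tissues_per_subject > 0)


def score_beta(fit: NullFit, g: GenotypeLike) -> float:
    """Efficient score for the cross-tissue fixed effect beta.

    Subjects with missing dosage are dropped from both the genotype and the
    residual term; the dosage mean is recomputed over the retained subjects.
    """
    d = _dosages(g)
    keep = _retained(fit, d)
    if not keep.any():
        return 0.0
    gk = d[keep] - d[keep].mean()
    row_w = fit.weighted_residuals[keep].sum(axis=1)
    return float(gk @ row_w)


def score_gamma(fit: NullFit, g: GenotypeLike) -> float:
    """Efficient score for the tissue-specific interaction variance gamma.

    Equals ``1/2 * r' Sigma^-1 X X' Sigma^-1 r``; with ``w = Sigma^-1 r``
    this is ``1/2 * sum_s (sum_i g_i w_is)^2``, nonnegative by construction.
    """
    d = _dosages(g)
    keep = _retained(fit, d)
    if not keep.any():
        return 0.0
    q = d[keep] @ fit.weighted_residuals[keep]
    return 0.5 * float(q @ q)


@dataclass(frozen=True)
class ScoreMoments:
    """Exact null moments of the score components.

    ``var_u_beta`` is Var(U_beta) = E[U_beta^2]; the squared score then has
    Var(U_beta^2) = 2*Var(U_beta)^2.  U_gamma is a quadratic form in the
    projected residuals, so its mean/variance are trace formulas, and
    ``cov_ubeta2_ugamma`` is the null covariance of U_beta^2 with U_gamma.
    """

    var_u_beta: float
    e_u_gamma: float
    var_u_gamma: float
    cov_ubeta2_ugamma: float

    @property
    def e_u_beta_sq(self) -> float:
        return self.var_u_beta

    @property
    def var_u_beta_sq(self) -> float:
        return 2.0 * self.var_u_beta**2


def null_moments(fit: NullFit, g: GenotypeLike) -> ScoreMoments:
    """Null moments of U_beta^2 and U_gamma under the fitted null.

    Both statistics are (quadratic) functions of r = Y - J*alpha_hat, whose
    null covariance is the projected ``V = Sigma - J (J'Sigma^-1 J)^-1 J'``.
    For a Gaussian quadratic form r'Ar with r ~ N(0, V): E = tr(AV) and
    Var = 2 tr(AVAV); all traces reduce to t x t matrix algebra via the
    Woodbury blocks (subjects with missing dosage are dropped from the SNP
    design but alpha-projection information keeps all subjects).
    """
    d = _dosages(g)
    keep = _retained(fit, d)
    eps = fit.cov.epsilon
    mfl = fit.mask.astype(float)

    mk = mfl[keep]
    dk = d[keep]
    ek = dk - dk.mean()
    ck = fit.shrink[keep]
    tk = fit.tissues_per_subject[keep]
    denom = eps + tk * fit.cov.tau  # = eps / (1 - c*t_i)

    # t x t building blocks, summed over retained subjects
    def _weighted_quad(wts):
        # sum_i wts_i * S_i' Sigma_i^-1 S_i  =  (1/eps) * (diag(sum wts*m) - M' diag(wts*c) M)
        return (np.diag(mk.T @ wts) - (mk * (wts * ck)[:, None]).T @ mk) / eps

    xmx = _weighted_quad(dk * dk)  # X' Sigma^-1 X
    kmat = _weighted_quad(dk)      # X' Sigma^-1 J
    gmg = float((ek * ek * tk / denom).sum())      # (G-Gbar)' Sigma^-1 (G-Gbar)
    h = (ek / denom) @ mk                          # J' Sigma^-1 (G-Gbar)
    xmg = ((dk * ek) / denom) @ mk                 # X' Sigma^-1 (G-Gbar)

    B = fit.info_alpha_inv  # (J' Sigma^-1 J)^-1 over *all* subjects

    var_u_beta = gmg - float(h @ B @ h)
    Q = xmx - kmat @ B @ kmat.T  # X' Sigma^-1 V Sigma^-1 X
    e_u_gamma = 0.5 * float(np.trace(Q))
    var_u_gamma = 0.5 * float((Q * Q.T).sum())  # = 1/2 tr(Q @ Q), Q symmetric
    dvec = xmg - kmat @ B @ h
    cov = float(dvec @ dvec)

    return ScoreMoments(
        var_u_beta=max(var_u_beta, 0.0),
        e_u_gamma=max(e_u_gamma, 0.0),
        var_u_gamma=max(var_u_gamma, 0.0),
        cov_ubeta2_ugamma=max(cov, 0.0),
    )


def combine(
    u_beta: float,
    u_gamma: float,
    moments: ScoreMoments,
    rule: str = "inv_sd",
):
    """Weights and joint statistic U_psi = a_beta*U_beta^2 + a_gamma*U_gamma.

    The default ``inv_sd`` rule standardises each component by its null
    standard deviation, a_beta = 1/sd(U_beta^2) and a_gamma = 1/sd(U_gamma),
    so neither component dominates the variance of the sum.  Other callables
    mapping ScoreMoments -> (a_beta, a_gamma) may be supplied through
    :func:`joint_test`.
    """
    if rule != "inv_sd":
        raise ValueError(f"unknown weight rule {rule!r}")
    vb = moments.var_u_beta_sq
    vg = moments.var_u_gamma
    a_beta = 1.0 / np.sqrt(vb) if vb > 0 else 0.0
    a_gamma = 1.0 / np.sqrt(vg) if vg > 0 else 0.0
    u_psi = a_beta * u_beta * u_beta + a_gamma * u_gamma
    return float(a_beta), float(a_gamma), float(u_psi)


def _upsi_moments(a_beta: float, a_gamma: float, m: ScoreMoments):
    mean = a_beta * m.e_u_beta_sq + a_gamma * m.e_u_gamma
    var = (
        a_beta**2 * m.var_u_beta_sq
        + a_gamma**2 * m.var_u_gamma
        + 2.0 * a_beta * a_gamma * m.cov_ubeta2_ugamma
    )
    return float(mean), float(var)


def satterthwaite_p(u_psi: float, mean_upsi: float, var_upsi: float):
    """Scaled chi-square calibration by matching the first two moments.

    Solves kappa*nu = E[U_psi] and 2*kappa^2*nu = Var(U_psi), giving
    kappa = Var/(2E) and nu = 2E^2/Var; the p-value is the upper tail of
    chi^2_nu at u_psi/kappa, floored at the smallest positive double so it
    stays in (0, 1].
    """
    if not (mean_upsi > 0 and var_upsi > 0):
        raise ValueError("Satterthwaite moments must be positive")
    kappa = var_upsi / (2.0 * mean_upsi)
    nu = 2.0 * mean_upsi**2 / var_upsi
    p = float(stats.chi2.sf(u_psi / kappa, df=nu))
    return float(kappa), float(nu), max(p, _P_FLOOR)


@dataclass(frozen=True)
class JointScoreResult:
    """Everything the joint test produces for one gene-SNP pair."""

    u_beta: float
    u_gamma: float
    a_beta: float
    a_gamma: float
    u_psi: float
    mean_upsi: float
    var_upsi: float
    kappa: float
    nu: float
    p_value: float
    flag: str = ""  # "" (clean) or "monomorphic"


def joint_test(
    fit: NullFit,
    g: GenotypeLike,
    weight_rule: str = "inv_sd",
) -> JointScoreResult:
    """Joint score test of H0: beta = gamma = 0 for one gene-SNP pair.

    Degenerate genotypes (fewer than two distinct observed dosages) are
    flagged and given p = 1 so callers can exclude them from multiplicity
    counts.  Many SNPs can share one fit; the per-SNP cost is O(n*t).
    """
    d = _dosages(g)
    keep = _retained(fit, d)
    if np.unique(d[keep]).size < 2:
        return JointScoreResult(
            u_beta=0.0, u_gamma=0.0, a_beta=0.0, a_gamma=0.0, u_psi=0.0,
            mean_upsi=np.nan, var_upsi=np.nan, kappa=np.nan, nu=np.nan,
            p_value=1.0, flag="monomorphic",
        )
    ub = score_beta(fit, d)
    ug = score_gamma(fit, d)
    mom = null_moments(fit, d)
    a_b, a_g, u_psi = combine(ub, ug, mom, rule=weight_rule)
    mean, var = _upsi_moments(a_b, a_g, mom)
    kappa, nu, p = satterthwaite_p(u_psi, mean, var)
    return JointScoreResult(
        u_beta=ub, u_gamma=ug, a_beta=a_b, a_gamma=a_g, u_psi=u_psi,
        mean_upsi=mean, var_upsi=var, kappa=kappa, nu=nu, p_value=p,
    )
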