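"""Null model for the multi-tissue mixed model.

For subject ``i`` with observed tissues ``O_i`` the null (no-genotype) model is

    y_i = alpha_{O_i} + u_i * 1 + xi_i,   u_i ~ N(0, tau),  xi ~ N(0, epsilon*I)

so the marginal covariance of each subject block is the compound-symmetry
matrix ``Sigma_i = epsilon*I + tau*11'``.  The null is fitted once per gene by
maximum likelihood: the tissue intercepts ``alpha`` are profiled out in closed
form (GLS) and the two variance components are maximised numerically on the
log scale, or — for balanced complete data — recovered exactly from the
spectral decomposition of the compound-symmetry block.

Everything downstream (score tests, permutations) consumes the resulting
:class:`NullFit`, which caches the per-subject Woodbury pieces so that each
SNP test costs O(n*t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .containers import CovStructure, ExpressionBlock
from .errors import ConvergenceError, DegenerateDataError, InvalidCovarianceError

__all__ = ["NullFit", "fit_null", "block_inverse", "profile_loglik"]

_LOG2PI = math.log(2.0 * math.pi)

# tau-hat below this multiple of epsilon-hat is snapped to the boundary tau = 0,
# keeping the boundary case explicit for the score test.
_TAU_BOUNDARY_FACTOR = 1e-8


def block_inverse(cov: CovStructure, t_i: int) -> np.ndarray:
    """Inverse of one subject's covariance block ``epsilon*I + tau*11'``.

    Uses the Woodbury identity: ``(1/epsilon) * (I - c*11')`` with
    ``c = tau/(epsilon + t_i*tau)``.  Symmetric positive definite for any
    valid :class:`CovStructure`.
    """
    if t_i < 1:
        raise ValueError("t_i must be >= 1")
    c = float(cov.shrink(t_i))
    eye = np.eye(t_i)
    return (eye - c * np.ones((t_i, t_i))) / cov.epsilon


def _prepare(expr: ExpressionBlock):
    """Zero-filled values, float mask, per-subject observed counts."""
    mask = expr.mask
    y0 = np.where(mask, expr.values, 0.0)
    mfl = mask.astype(float)
    t_i = mfl.sum(axis=1)
    return y0, mfl, t_i


def _gls_alpha(y0, mfl, t_i, tau, eps):
    """Profiled GLS intercepts alpha(tau, eps).

    Solves (J' Sigma^-1 J) alpha = J' Sigma^-1 Y using the Woodbury block
    form; the common 1/eps factor cancels.
    """
    c = tau / (eps + t_i * tau)
    info = np.diag(mfl.sum(axis=0)) - (mfl * c[:, None]).T @ mfl
    rhs = y0.sum(axis=0) - mfl.T @ (c * y0.sum(axis=1))
    try:
        return np.linalg.solve(info, rhs)
    except np.linalg.LinAlgError as e:  # a tissue with zero observations
        raise DegenerateDataError("tissue with no observed subjects") from e


def _loglik_at(y0, mfl, t_i, tau, eps):
    """Observed-data log-likelihood at (alpha_gls(tau,eps), tau, eps)."""
    alpha = _gls_alpha(y0, mfl, t_i, tau, eps)
    r = (y0 - alpha) * mfl
    rows = r.sum(axis=1)
    c = tau / (eps + t_i * tau)
    quad = ((r * r).sum() - (c * rows * rows).sum()) / eps
    # |eps*I + tau*11'| = eps^(t_i-1) * (eps + t_i*tau); the t_i = 0 terms cancel
    logdet = ((t_i - 1.0) * math.log(eps)).sum() + np.log(eps + t_i * tau).sum()
    n_obs = mfl.sum()
    return -0.5 * (n_obs * _LOG2PI + logdet + quad), alpha, r


def profile_loglik(expr: ExpressionBlock, cov: CovStructure) -> float:
    """Log-likelihood at (alpha_gls(tau,eps), tau, eps) for the null model."""
    y0, mfl, t_i = _prepare(expr)
    ll, _, _ = _loglik_at(y0, mfl, t_i, cov.tau, cov.epsilon)
    return float(ll)


@dataclass
class NullFit:
    """Fitted null model plus cached structured-inverse pieces.

    Attributes with a trailing context: ``weighted_residuals`` is
    ``Sigma_hat^{-1} (Y - J alpha_hat)`` stored subject-major with zeros at
    masked cells; ``info_alpha_inv`` is ``(J' Sigma^-1 J)^{-1}``, needed for
    the alpha-projection of the score-test null moments.
    """

    alpha_hat: np.ndarray
    cov: CovStructure
    loglik: float
    residuals: np.ndarray  # (n, t), NaN at masked cells
    mask: np.ndarray
    subject_ids: list
    tissue_ids: list
    n_iter: int = 0
    # caches (computed in __post_init__)
    tissues_per_subject: np.ndarray = field(init=False)
    shrink: np.ndarray = field(init=False)
    weighted_residuals: np.ndarray = field(init=False)
    info_alpha_inv: np.ndarray = field(init=False)

    def __post_init__(self):
        mfl = self.mask.astype(float)
        t_i = mfl.sum(axis=1)
        c = self.cov.shrink(t_i)
        r0 = np.where(self.mask, self.residuals, 0.0)
        w = (r0 - (c * r0.sum(axis=1))[:, None] * mfl) / self.cov.epsilon
        info = (np.diag(mfl.sum(axis=0)) - (mfl * c[:, None]).T @ mfl) / self.cov.epsilon
        self.tissues_per_subject = t_i
        self.shrink = c
        self.weighted_residuals = w
        self.info_alpha_inv = np.linalg.inv(info)

    @property
    def n_subjects(self) -> int:
        return self.residuals.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.residuals.shape[1]


def _balanced_mle(y0, mfl, t_i):
    """Exact ML for complete balanced data via the CS spectral decomposition.

    With all blocks complete, alpha_hat is the per-tissue mean and the
    likelihood separates along the eigenspaces of ``eps*I + tau*11'``
    (eigenvalues ``eps + t*tau`` on the equal-weight direction, ``eps`` on
    its complement), giving closed-form variance estimates.
    """
    n, t = y0.shape
    alpha = y0.mean(axis=0)
    r = y0 - alpha
    rbar = r.mean(axis=1)
    lam1 = t * np.mean(rbar * rbar)  # MLE of eps + t*tau
    if t > 1:
        ssw = (r * r).sum() - t * (rbar * rbar).sum()
        eps = ssw / (n * (t - 1))
    else:
        eps = lam1
    tau = max((lam1 - eps) / t, 0.0)
    if tau <= _TAU_BOUNDARY_FACTOR * eps or t == 1:
        tau = 0.0
        eps = (r * r).sum() / (n * t)
    return tau, eps


def fit_null(expr: ExpressionBlock, tol: float = 1e-8, max_iter: int = 200) -> NullFit:
    """Maximum-likelihood null fit (no genotype terms) of one gene.

    Parameters
    ----------
    expr : ExpressionBlock
        Per-gene expression with missingness mask.  Subjects with no
        observed tissue contribute nothing and are tolerated.
    tol : float
        Relative log-likelihood convergence tolerance of the variance
        optimiser.
    max_iter : int
        Iteration cap; exceeding it raises :class:`ConvergenceError`
        carrying the iteration trace.

    Returns
    -------
    NullFit
        MLEs (alpha_hat, tau_hat, eps_hat), achieved log-likelihood,
        residuals, and cached Woodbury pieces.  ``tau_hat`` sits exactly at
        0 when the optimum is on the boundary.
    """
    y0, mfl, t_i = _prepare(expr)
    obs = expr.values[expr.mask]
    if obs.size == 0 or np.var(obs) < 1e-300:
        raise DegenerateDataError("expression has zero variance; null model undefined")
    if int((t_i >= 2).sum()) < 2:
        raise DegenerateDataError(
            "need >= 2 subjects with >= 2 observed tissues to identify tau"
        )

    balanced = bool(expr.mask.all())
    if balanced:
        tau, eps = _balanced_mle(y0, mfl, t_i)
        n_iter = 0
    else:
        tau, eps, n_iter = _optimize_unbalanced(y0, mfl, t_i, tol, max_iter)

    cov = CovStructure(tau=tau, epsilon=eps)
    ll, alpha, r = _loglik_at(y0, mfl, t_i, tau, eps)
    residuals = np.where(expr.mask, expr.values - alpha, np.nan)
    return NullFit(
        alpha_hat=alpha,
        cov=cov,
        loglik=float(ll),
        residuals=residuals,
        mask=expr.mask,
        subject_ids=list(expr.subject_ids),
        tissue_ids=list(expr.tissue_ids),
        n_iter=n_iter,
    )


def _tau0_candidate(y0, mfl, t_i):
    """Closed-form boundary candidate: tau = 0, per-tissue means, eps = RSS/N."""
    counts = mfl.sum(axis=0)
    counts = np.where(counts > 0, counts, 1.0)
    alpha = y0.sum(axis=0) / counts
    r = (y0 - alpha) * mfl
    eps = (r * r).sum() / mfl.sum()
    return max(eps, 1e-300)


def _profile_grad(y0, mfl, t_i, tau, eps):
    """Analytic gradient of the alpha-profiled log-likelihood in (tau, eps).

    By the envelope theorem the alpha-hat dependence drops out at the GLS
    optimum, leaving the standard variance-component score contributions
    per subject block.
    """
    alpha = _gls_alpha(y0, mfl, t_i, tau, eps)
    r = (y0 - alpha) * mfl
    rows = r.sum(axis=1)
    denom = eps + t_i * tau
    c = tau / denom
    # d/dtau: 1/2 sum_i [(1' Sigma_i^-1 r_i)^2 - tr(Sigma_i^-1 11')]
    g_tau = 0.5 * ((rows / denom) ** 2 - t_i / denom).sum()
    # d/deps: 1/2 sum_i [w_i'w_i - tr(Sigma_i^-1)]
    rss = (r * r).sum(axis=1)
    wtw = (rss - (2 * c - c * c * t_i) * rows * rows) / eps**2
    tr_inv = (t_i - 1.0) / eps + 1.0 / denom
    g_eps = 0.5 * (wtw - tr_inv).sum()
    return g_tau, g_eps


def _optimize_unbalanced(y0, mfl, t_i, tol, max_iter):
    """Bounded quasi-Newton maximisation over (log tau, log eps)."""
    var0 = float(np.var(y0[mfl.astype(bool)]))
    trace = []

    def neg(theta):
        tau, eps = np.exp(theta)
        ll, _, _ = _loglik_at(y0, mfl, t_i, tau, eps)
        trace.append((tau, eps, ll))
        g_tau, g_eps = _profile_grad(y0, mfl, t_i, tau, eps)
        return -ll, -np.array([g_tau * tau, g_eps * eps])  # chain rule, log scale

    lo, hi = math.log(var0) - 25.0, math.log(var0) + 8.0
    x0 = np.array([math.log(max(var0 / 4.0, 1e-12)), math.log(max(var0 / 2.0, 1e-12))])
    res = optimize.minimize(
        neg,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(lo, hi), (lo, hi)],
        # run a few orders tighter than the declared tolerance so the
        # variance components are accurate well beyond tol in log-likelihood
        options={"maxiter": max_iter, "ftol": tol * 1e-4, "gtol": 1e-12},
    )
    if not res.success and res.status == 1:  # hit the iteration cap
        raise ConvergenceError(
            f"null fit did not converge in {max_iter} iterations", trace=trace
        )
    tau, eps = np.exp(res.x)
    ll_opt = -res.fun

    # boundary candidate tau = 0 (log-parametrisation cannot reach it exactly)
    eps0 = _tau0_candidate(y0, mfl, t_i)
    ll0, _, _ = _loglik_at(y0, mfl, t_i, 0.0, eps0)
    if ll0 >= ll_opt or tau <= _TAU_BOUNDARY_FACTOR * eps:
        return 0.0, float(eps0), int(res.nit)
    return float(tau), float(eps), int(res.nit)
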