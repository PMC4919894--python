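"""Dense-matrix reference implementations used as independent oracles.

Everything here assembles the full nt x nt covariance explicitly and uses
generic numpy/scipy linear algebra and optimisers, deliberately sharing no
code with the package's structured O(nt) path.
"""

import math

import numpy as np
from scipy import optimize

from tissueqtl import ExpressionBlock

LOG2PI = math.log(2.0 * math.pi)


def sim_block(n, t, tau, eps, rng, alpha=None, missing=0.0):
    """Null-model draw: y_is = alpha_s + u_i + e_is, optional random masking."""
    alpha = np.zeros(t) if alpha is None else np.asarray(alpha, float)
    y = alpha + rng.normal(0, np.sqrt(tau), n)[:, None] + rng.normal(0, np.sqrt(eps), (n, t))
    mask = None
    if missing > 0:
        mask = rng.random((n, t)) >= missing
        # keep the fit identifiable: first two subjects fully observed
        mask[:2] = True
    return ExpressionBlock(values=y, mask=mask)


def stacked_rows(mask):
    n, t = mask.shape
    return [(i, s) for i in range(n) for s in range(t) if mask[i, s]]


def dense_pieces(mask):
    """Dense design matrices J (N x t) and Z (N x n) over observed cells."""
    rows = stacked_rows(mask)
    n, t = mask.shape
    N = len(rows)
    J = np.zeros((N, t))
    Z = np.zeros((N, n))
    for k, (i, s) in enumerate(rows):
        J[k, s] = 1.0
        Z[k, i] = 1.0
    return J, Z, rows


def dense_sigma(mask, tau, eps):
    J, Z, rows = dense_pieces(mask)
    return eps * np.eye(len(rows)) + tau * (Z @ Z.T)


def dense_loglik(values, mask, alpha, tau, eps):
    """Gaussian log-likelihood with explicitly assembled Sigma."""
    J, Z, rows = dense_pieces(mask)
    y = np.array([values[i, s] for i, s in rows])
    Sigma = eps * np.eye(len(rows)) + tau * (Z @ Z.T)
    r = y - J @ np.asarray(alpha, float)
    sign, logdet = np.linalg.slogdet(Sigma)
    return -0.5 * (len(rows) * LOG2PI + logdet + r @ np.linalg.solve(Sigma, r))


def dense_fit(values, mask, maxiter=4000):
    """Generic Nelder-Mead ML fit over (alpha, log tau, log eps)."""
    t = mask.shape[1]
    means = np.array([values[:, s][mask[:, s]].mean() for s in range(t)])
    var0 = np.nanvar(np.where(mask, values, np.nan))

    def neg(theta):
        alpha, ltau, leps = theta[:t], theta[t], theta[t + 1]
        return -dense_loglik(values, mask, alpha, math.exp(ltau), math.exp(leps))

    x0 = np.concatenate([means, [math.log(var0 / 3), math.log(var0 / 2)]])
    res = optimize.minimize(
        neg, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-10, "fatol": 1e-12},
    )
    alpha = res.x[:t]
    return alpha, math.exp(res.x[t]), math.exp(res.x[t + 1]), -res.fun


def dense_scores(values, mask, dosages, alpha, tau, eps):
    """Scores and null moments from explicit Sigma, J, X assembly.

    Subjects with missing dosage are excluded from the SNP design; the
    intercept information uses all observed cells.
    """
    J, Z, rows = dense_pieces(mask)
    y = np.array([values[i, s] for i, s in rows])
    Sigma = eps * np.eye(len(rows)) + tau * (Z @ Z.T)
    Minv = np.linalg.inv(Sigma)
    B = np.linalg.inv(J.T @ Minv @ J)

    d = np.asarray(dosages, float)
    keep_subject = np.isfinite(d)
    keep_rows = np.array([keep_subject[i] for i, s in rows])
    R = np.flatnonzero(keep_rows)
    gbar = d[keep_subject & (mask.sum(axis=1) > 0)].mean()

    t = mask.shape[1]
    Gc = np.array([d[i] - gbar for i, s in np.array(rows)[R]])
    X = np.zeros((len(R), t))
    for k, ridx in enumerate(R):
        i, s = rows[ridx]
        X[k, s] = d[i]

    Sig_R = Sigma[np.ix_(R, R)]
    M_R = np.linalg.inv(Sig_R)
    J_R = J[R]
    r_R = (y - J @ np.asarray(alpha, float))[R]

    u_beta = Gc @ M_R @ r_R
    u_gamma = 0.5 * r_R @ M_R @ X @ X.T @ M_R @ r_R

    V = Sig_R - J_R @ B @ J_R.T
    c = M_R @ Gc
    A = 0.5 * M_R @ X @ X.T @ M_R
    var_u_beta = c @ V @ c
    AV = A @ V
    e_u_gamma = np.trace(AV)
    var_u_gamma = 2.0 * np.trace(AV @ AV)
    cov = 2.0 * c @ V @ A @ V @ c
    return {
        "u_beta": u_beta,
        "u_gamma": u_gamma,
        "var_u_beta": var_u_beta,
        "e_u_gamma": e_u_gamma,
        "var_u_gamma": var_u_gamma,
        "cov_ubeta2_ugamma": cov,
        "V": V,
    }
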