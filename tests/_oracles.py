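"""Independent reference implementations used to check the package.

Everything here is deliberately naive (element loops, generic convex
optimisation, textbook formulas) and shares no code with the library.
"""

import numpy as np
import scipy.linalg
from scipy.optimize import minimize


def polar_orthonormal(Z):
    """Closest orthonormal matrix via the matrix square root, Z (ZᵀZ)^{-1/2}."""
    G = Z.T @ Z
    return Z @ np.linalg.inv(scipy.linalg.sqrtm(G))


def frobenius_error_loop(Z, P):
    """Element-by-element sum of squared differences."""
    total = 0.0
    for i in range(Z.shape[0]):
        for j in range(Z.shape[1]):
            total += (Z[i, j] - P[i, j]) ** 2
    return total


def gram_schmidt_error(Z, order):
    """ε of sequentially orthogonalising columns of Z in the given order.

    The first column is kept; each later column is replaced by its
    residual after projecting out all previously kept columns.
    """
    m, n = Z.shape
    kept = []
    err = 0.0
    for idx in order:
        v = Z[:, idx].copy()
        for u in kept:
            v -= (u @ Z[:, idx]) / (u @ u) * u
        err += np.sum((Z[:, idx] - v) ** 2)
        kept.append(v)
    return err


def partial_corr_by_residualisation(S):
    """Partial correlations via explicit pairwise regression residuals.

    For each pair (i, j): regress variables i and j on all remaining
    variables (population regression from the covariance), and correlate
    the residuals.
    """
    n = S.shape[0]
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rest = [k for k in range(n) if k not in (i, j)]
            if rest:
                Srr = S[np.ix_(rest, rest)]
                bi = np.linalg.solve(Srr, S[rest, i])
                bj = np.linalg.solve(Srr, S[rest, j])
                var_i = S[i, i] - S[i, rest] @ bi
                var_j = S[j, j] - S[j, rest] @ bj
                cov_ij = S[i, j] - S[i, rest] @ bj
            else:
                var_i, var_j, cov_ij = S[i, i], S[j, j], S[i, j]
            rho[i, j] = rho[j, i] = cov_ij / np.sqrt(var_i * var_j)
    return rho


def blackbox_glasso(S, lam, penalize_diagonal=True):
    """General-purpose convex optimiser for the graphical-lasso objective.

    Splits Ω into positive and negative parts so the objective is smooth
    with bound constraints, and runs L-BFGS-B to tight tolerances from
    two starting points, restarting until no further progress.
    """
    n = S.shape[0]
    iu = np.triu_indices(n)
    diag = iu[0] == iu[1]
    mult = np.where(diag, 1.0, 2.0)  # off-diagonals appear twice in Omega
    pen_w = np.where(diag, lam if penalize_diagonal else 0.0, lam * 2.0)

    def unpack(theta):
        k = len(iu[0])
        p, q = theta[:k], theta[k:]
        O = np.zeros((n, n))
        O[iu] = p - q
        O = O + np.triu(O, 1).T
        return O, p, q

    def fun(theta):
        O, p, q = unpack(theta)
        w = np.linalg.eigvalsh(O)
        if w.min() <= 1e-12:
            return 1e6 - 1e4 * w.min(), np.zeros_like(theta)
        _, ld = np.linalg.slogdet(O)
        f = -ld + np.sum(S * O) + np.sum(pen_w * (p + q))
        G = -np.linalg.inv(O) + S
        g = mult * G[iu]
        return f, np.concatenate([g + pen_w, -g + pen_w])

    opts = dict(maxiter=50000, ftol=1e-18, gtol=1e-14, maxls=100, maxcor=30)
    bounds = [(0, None)] * (2 * len(iu[0]))
    best, bf = None, np.inf
    for M in (np.eye(n), np.linalg.inv(S + 0.1 * np.eye(n))):
        v = M[iu]
        x0 = np.concatenate([np.maximum(v, 0), np.maximum(-v, 0)])
        res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds, options=opts)
        for _ in range(20):
            res2 = minimize(
                fun, res.x, jac=True, method="L-BFGS-B", bounds=bounds, options=opts
            )
            if res2.fun >= res.fun - 1e-12:
                break
            res = res2
        if res.fun < bf:
            bf, best = res.fun, res.x
    return unpack(best)[0]
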