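"""Gaussian-graphical network inference on power envelopes.

Envelope co-modulation between nodes is modelled as a zero-mean
multivariate Gaussian with precision (inverse covariance) matrix Ω.
Direct (conditional) connections are read from the partial-correlation
matrix

    ρ⊥ = −diag(Ω)^{−1/2} Ω diag(Ω)^{−1/2},

whose zeros mark conditional independence.  Because sample partial
correlations are noisy, the precision can be estimated with an L1
penalty (graphical lasso):

    Ω̂ = argmax_{Ω ≻ 0}  log det Ω − tr(S Ω) − λ‖Ω‖₁,

where the penalty covers the whole matrix including the diagonal (a
``penalize_diagonal=False`` switch matches the more common off-diagonal
convention).  λ is chosen by k-fold cross-validation on contiguous
temporal blocks, minimising a corrected Akaike criterion on the held-out
blocks, with the search grid refined around the incumbent.

Edge statistics are Fisher-transformed and scaled by the standard
deviation of an empirical null — AR(1) surrogate data matched in node
count and temporal smoothness, pushed through the same envelope
pipeline — so that they are standard normal when no connection exists.
Group inference is fixed-effects (mean over subjects times √S), and
multiplicity is controlled with a Benjamini–Hochberg FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import envelope as env_mod
from . import simulate as sim_mod
from .errors import ParameterError, ShapeError, SolverError

__all__ = [
    "NetworkEstimate",
    "CalibratedZMatrix",
    "partial_correlation",
    "graphical_lasso",
    "glasso_objective",
    "select_lambda",
    "fisher_z",
    "null_scaling",
    "group_fixed_effects",
    "fdr_threshold",
    "network_estimate",
    "edge_values",
]

METRICS = ("full", "partial", "partial_regularised")


@dataclass
class NetworkEstimate:
    """Covariance, precision and partial-correlation view of one dataset."""

    covariance: np.ndarray
    precision: np.ndarray
    partial_correlation: np.ndarray
    lambda_: float
    metric: str


@dataclass
class CalibratedZMatrix:
    """Edge z-scores scaled to be standard normal under the null."""

    z: np.ndarray
    null_sd: float
    n_subjects: int = 1


def partial_correlation(omega) -> np.ndarray:
    """Partial correlations from a precision matrix.

    Off-diagonals are ``−Ω_ij / sqrt(Ω_ii Ω_jj)``; the diagonal is set to
    1 by convention.
    """
    omega = np.asarray(omega, dtype=float)
    d = np.diag(omega)
    if np.any(d <= 0):
        raise ParameterError("precision matrix must have a strictly positive diagonal")
    inv_sqrt = 1.0 / np.sqrt(d)
    rho = -omega * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(rho, 1.0)
    return rho


def glasso_objective(omega, S, lam: float, penalize_diagonal: bool = True) -> float:
    """Penalised negative log-likelihood ``−logdet Ω + tr(SΩ) + λ‖Ω‖₁``.

    (The graphical-lasso maximand times −1; lower is better.)
    """
    omega = np.asarray(omega, dtype=float)
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return np.inf
    l1 = np.abs(omega).sum()
    if not penalize_diagonal:
        l1 -= np.abs(np.diag(omega)).sum()
    return float(-logdet + np.sum(S * omega) + lam * l1)


def _soft_threshold(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def graphical_lasso(
    S,
    lam: float,
    penalize_diagonal: bool = True,
    tol: float = 1e-8,
    max_iter: int = 2000,
    rho: float = 1.0,
) -> np.ndarray:
    """L1-penalised precision estimate by ADMM.

    Solves ``min −logdet Ω + tr(SΩ) + λ‖Ω‖₁`` over positive-definite Ω.
    The Ω-subproblem is solved exactly by eigendecomposition; the penalty
    subproblem by soft-thresholding.  Convergence is declared when both
    primal and dual residuals fall below ``tol`` (scaled by matrix size).

    Raises
    ------
    SolverError
        If residuals have not converged within ``max_iter`` sweeps.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ShapeError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ShapeError("covariance must be symmetric")
    if lam < 0:
        raise ParameterError("lambda must be nonnegative")
    n = S.shape[0]

    if lam == 0.0:
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e12:
            raise ParameterError(
                "lambda = 0 requires a non-singular covariance (condition "
                f"number {cond:.3e})"
            )
        return np.linalg.inv(S)

    Theta = np.eye(n)
    Z = np.eye(n)
    U = np.zeros((n, n))
    scale = n  # residual normalisation
    for _ in range(max_iter):
        # Theta-step: −logdet Θ + tr(SΘ) + (rho/2)‖Θ − Z + U‖² minimised in closed form
        G = rho * (Z - U) - S
        G = (G + G.T) / 2.0
        gamma, Q = np.linalg.eigh(G)
        theta_eig = (gamma + np.sqrt(gamma**2 + 4.0 * rho)) / (2.0 * rho)
        Theta = (Q * theta_eig) @ Q.T
        # Z-step: soft-threshold
        Z_old = Z
        V = Theta + U
        Z = _soft_threshold(V, lam / rho)
        if not penalize_diagonal:
            np.fill_diagonal(Z, np.diag(V))
        U = U + Theta - Z
        r_primal = np.linalg.norm(Theta - Z) / scale
        r_dual = rho * np.linalg.norm(Z - Z_old) / scale
        if r_primal < tol and r_dual < tol:
            break
    else:
        raise SolverError(
            f"graphical lasso ADMM did not converge in {max_iter} iterations "
            f"(primal residual {r_primal:.3e}, dual residual {r_dual:.3e})"
        )
    # return the thresholded iterate: exact zeros encode the support
    Z = (Z + Z.T) / 2.0
    # guard: ensure positive definiteness of the reported estimate
    w = np.linalg.eigvalsh(Z)
    if w.min() <= 0:
        return (Theta + Theta.T) / 2.0
    return Z


def _fold_bounds(n_samples: int, folds: int):
    edges = np.linspace(0, n_samples, folds + 1).round().astype(int)
    return [(edges[i], edges[i + 1]) for i in range(folds)]


def select_lambda(
    envelopes,
    folds: int = 10,
    refinements: int = 3,
    grid=None,
    penalize_diagonal: bool = True,
) -> float:
    """Cross-validated regularisation strength for the graphical lasso.

    The envelope samples are split into ``folds`` contiguous temporal
    blocks (envelopes are autocorrelated, so random folds would leak
    information across the split).  For each grid value the precision is
    fitted on the training blocks, the held-out log-likelihood is pooled
    over folds, and the corrected Akaike criterion

        AICc = −2·loglik_heldout + 2k + 2k(k+1)/(m − k − 1)

    is minimised, with ``k`` counting the free parameters of the fitted
    support (the diagonal plus the union of nonzero upper-triangle
    entries across fold fits) and ``m`` the pooled held-out sample count.
    Supports richer than the data allow (``m ≤ k + 1``) score +inf.  The
    (geometric) grid is zoomed around the minimiser ``refinements``
    times, shrinking its log-width by a factor of 4 each time.
    """
    X = np.asarray(getattr(envelopes, "values", envelopes), dtype=float)
    m, n = X.shape
    if m < 5 * folds:
        raise ParameterError(f"need at least 5 samples per fold, got {m} for {folds} folds")
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    bounds = _fold_bounds(m, folds)
    if grid is None:
        grid = np.geomspace(1e-4, 1.0, 16)
    grid = np.asarray(grid, dtype=float)

    def cv_score(lam: float) -> float:
        ll_total = 0.0
        m_total = 0
        support = np.zeros((n, n), dtype=bool)
        for lo, hi in bounds:
            val = X[lo:hi]
            train = np.vstack([X[:lo], X[hi:]])
            n_val = val.shape[0]
            if val.std(axis=0).min() < 1e-12 or train.std(axis=0).min() < 1e-12:
                continue  # degenerate fold: skip
            S_train = np.cov(train, rowvar=False, ddof=1)
            try:
                omega = graphical_lasso(S_train, lam, penalize_diagonal=penalize_diagonal)
            except (SolverError, ParameterError):
                return np.inf
            S_val = (val.T @ val) / n_val
            sign, logdet = np.linalg.slogdet(omega)
            ll_total += 0.5 * n_val * (logdet - np.sum(S_val * omega) - n * np.log(2 * np.pi))
            support |= omega != 0
            m_total += n_val
        if m_total == 0:
            raise ParameterError("all cross-validation folds were degenerate")
        nnz = int(np.count_nonzero(np.triu(support, k=1)))
        k = n + nnz
        if m_total - k - 1 <= 0:
            return np.inf
        return -2.0 * ll_total + 2.0 * k + 2.0 * k * (k + 1) / (m_total - k - 1)

    current = grid
    best = None
    for level in range(refinements + 1):
        scores = [cv_score(l) for l in current]
        best = float(current[int(np.argmin(scores))])
        if level == refinements:
            break
        log_width = (np.log(current[-1]) - np.log(current[0])) / 4.0
        current = np.geomspace(
            best * np.exp(-log_width / 2.0), best * np.exp(log_width / 2.0), len(grid)
        )
    return best


def fisher_z(r):
    """Fisher variance-stabilising transform ``arctanh(r)``."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ParameterError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _edge_r(S_or_rho, metric: str, lam: float = 0.0, penalize_diagonal: bool = True):
    """Edge correlation values from a covariance matrix, per metric."""
    S = np.asarray(S_or_rho, dtype=float)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    if metric == "full":
        return R
    if metric == "partial":
        omega = np.linalg.inv(R)
        return partial_correlation(omega)
    if metric == "partial_regularised":
        omega = graphical_lasso(R, lam, penalize_diagonal=penalize_diagonal)
        return partial_correlation(omega)
    raise ParameterError(f"unknown metric {metric!r}; expected one of {METRICS}")


def null_scaling(
    n_nodes: int,
    n_envelope_samples: int,
    ar1: float,
    metric: str = "full",
    n_null: int = 50,
    seed=None,
) -> float:
    """Standard deviation of the empirical null edge distribution.

    Simulates ``n_null`` datasets of independent Gaussian AR(1) series —
    matched to the node envelopes in count, length and temporal
    smoothness (their first autoregressive coefficient) — and takes full
    (or unregularised partial) correlations between them, exactly as the
    pipeline correlates the down-sampled envelopes.  The pooled standard
    deviation of the Fisher-transformed null edges is returned; dividing
    observed edge z-scores by it makes them standard normal when no
    connection exists.

    Matching the surrogates to the envelopes (rather than to the fast
    raw time-courses) is essential: envelope smoothness is dominated by
    the slow amplitude dynamics, and it is that smoothness which sets
    the sampling spread of envelope correlations.
    """
    if n_null < 20:
        raise ParameterError("need at least 20 null datasets")
    if not abs(ar1) < 1:
        raise ParameterError("|ar1| must be < 1")
    metric_key = "partial" if metric.startswith("partial") else "full"
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    iu = np.triu_indices(n_nodes, k=1)
    pooled = []
    for child in ss.spawn(n_null):
        X = sim_mod.ar1_null(n_nodes, n_envelope_samples, ar1, seed=child)
        S = np.cov(X, rowvar=False, ddof=1)
        R = _edge_r(S, metric_key)
        pooled.append(fisher_z(np.clip(R[iu], -0.999999, 0.999999)))
    pooled = np.concatenate(pooled)
    return float(pooled.std(ddof=1))


def lag1_autocorrelation(values) -> float:
    """Mean first autoregressive coefficient across columns."""
    X = np.asarray(values, dtype=float)
    X = X - X.mean(axis=0)
    num = np.sum(X[1:] * X[:-1], axis=0)
    den = np.sum(X * X, axis=0)
    return float(np.mean(num / den))


def group_fixed_effects(z_stack) -> CalibratedZMatrix:
    """Fixed-effects combination: per-edge ``Σ_i z_i / √S``.

    With each subject's edge scores standard normal under the null, the
    combined score is again standard normal, and tests the group-mean
    effect.
    """
    mats = [np.asarray(getattr(z, "z", z), dtype=float) for z in z_stack]
    if not mats:
        raise ParameterError("empty subject stack")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ShapeError("subject z-matrices differ in shape")
    S = len(mats)
    group = np.sum(mats, axis=0) / np.sqrt(S)
    return CalibratedZMatrix(z=group, null_sd=1.0, n_subjects=S)


def fdr_threshold(z, q: float = 0.05):
    """Benjamini–Hochberg control of the edge false discovery rate.

    One-sided p-values are taken from positive z on the upper-triangle
    edges (or on a flat vector of edge scores) and thresholded by the BH
    step-up rule at level ``q``.  Returns ``(z_threshold, mask)`` where
    ``z_threshold`` is the smallest surviving z (``inf`` when nothing
    survives) and ``mask`` a boolean array matching the input layout
    (symmetric matrix for matrix input).
    """
    if not (0.0 < q < 1.0):
        raise ParameterError("q must lie in (0, 1)")
    zmat = np.asarray(getattr(z, "z", z), dtype=float)
    if zmat.ndim == 1:
        pvals = stats.norm.sf(zmat)
        reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
        thr = float(zmat[reject].min()) if reject.any() else float("inf")
        return thr, reject
    n = zmat.shape[0]
    iu = np.triu_indices(n, k=1)
    pvals = stats.norm.sf(zmat[iu])
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    mask = np.zeros_like(zmat, dtype=bool)
    mask[iu] = reject
    mask = mask | mask.T
    z_threshold = float(zmat[iu][reject].min()) if reject.any() else float("inf")
    return z_threshold, mask


def network_estimate(
    envelopes,
    metric: str = "partial_regularised",
    lambda_: float | None = None,
    folds: int = 10,
    refinements: int = 3,
    penalize_diagonal: bool = True,
) -> NetworkEstimate:
    """Fit the chosen connectivity metric to down-sampled envelopes.

    Envelope columns are standardised before the covariance is formed, so
    the covariance is a correlation matrix and λ values are comparable
    across datasets.  For ``partial_regularised`` with ``lambda_=None``
    the strength is chosen by :func:`select_lambda`.
    """
    X = np.asarray(getattr(envelopes, "values", envelopes), dtype=float)
    if metric not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}; expected one of {METRICS}")
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    S = np.cov(Xs, rowvar=False, ddof=1)
    lam = 0.0
    if metric == "partial_regularised":
        if lambda_ is None:
            lam = select_lambda(
                Xs, folds=folds, refinements=refinements, penalize_diagonal=penalize_diagonal
            )
        else:
            lam = float(lambda_)
        omega = graphical_lasso(S, lam, penalize_diagonal=penalize_diagonal)
    else:
        omega = np.linalg.inv(S)
    rho = partial_correlation(omega)
    return NetworkEstimate(
        covariance=S, precision=omega, partial_correlation=rho, lambda_=lam, metric=metric
    )


def edge_values(estimate: NetworkEstimate) -> np.ndarray:
    """Edge correlation matrix appropriate to the estimate's metric."""
    if estimate.metric == "full":
        return estimate.covariance
    return estimate.partial_correlation
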