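"""Zero-lag leakage correction by symmetric (Löwdin) orthogonalisation.

Linear mixing of source signals — e.g. the spatial spread of an ill-posed
inverse reconstruction — creates artefactual correlations between channel
time-courses at exactly zero temporal lag.  Because the artefact is linear
and instantaneous, it can be removed by replacing the ``m × n`` matrix of
time-courses ``Z`` with the closest (least-squares) set of mutually
orthogonal vectors ``P``.

Two corrections are provided:

* :func:`symmetric_orthogonalise` — the multivariate correction.  Writing
  ``P = O D`` with ``O`` orthonormal and ``D = diag(d)`` positive, the
  Frobenius distance ``ε = ‖Z − P‖²_F`` is minimised by a tandem iteration
  that alternates the closed-form updates ``O ← UVᵀ`` (from the SVD of
  ``Z D``, the symmetric/Löwdin orthogonalisation) and ``d ← diag(ZᵀO)``.
  The solution is unique for full-rank input, equivariant under channel
  re-ordering, and minimally displaced from the raw time-courses.

* :func:`pairwise_orthogonalise` — the older two-channel correction in
  which one time-course is regressed from the other; it depends on which
  channel is taken as the seed, and is retained for method comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import DegenerateInputError, ShapeError

__all__ = [
    "OrthogonalisedSet",
    "closest_orthonormal",
    "symmetric_orthogonalise",
    "reconstruction_error",
    "pairwise_orthogonalise",
]

#: Declare rank deficiency when sigma_min/sigma_max falls below this.
RANK_TOLERANCE = 1e-10

#: Relative change in the reconstruction error at which the tandem stops.
DEFAULT_TOLERANCE = 1e-10

DEFAULT_MAX_ITERATIONS = 50


@dataclass
class OrthogonalisedSet:
    """Result of the symmetric multivariate correction.

    Attributes
    ----------
    P : ndarray, shape (m, n)
        Corrected, mutually orthogonal time-courses, ``P = O @ diag(d)``.
    O : ndarray, shape (m, n)
        Orthonormal frame (``O.T @ O = I``).
    d : ndarray, shape (n,)
        Column magnitudes of the corrected time-courses.
    error_trace : list of float
        Reconstruction error ``ε = ‖Z − P‖²_F`` after each tandem
        iteration; non-increasing.
    iterations : int
        Number of tandem iterations performed.
    converged : bool
        Whether the relative change in ``ε`` fell below the tolerance
        before the iteration cap.  Non-convergence is reported here, not
        raised, so batch runs can continue.
    """

    P: np.ndarray
    O: np.ndarray
    d: np.ndarray
    error_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False

    @property
    def error(self) -> float:
        """Final reconstruction error ε."""
        return self.error_trace[-1] if self.error_trace else float("nan")


def _as_2d(Z) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ShapeError(f"expected a 2-D samples × nodes matrix, got ndim={Z.ndim}")
    if not np.all(np.isfinite(Z)):
        raise DegenerateInputError("input contains non-finite values")
    return Z


def closest_orthonormal(Z) -> np.ndarray:
    """Closest orthonormal matrix to ``Z`` in the Frobenius norm.

    For full-column-rank ``Z`` with thin SVD ``Z = U Σ Vᵀ`` the unique
    minimiser of ``‖Z − O‖_F`` over orthonormal ``O`` is the polar factor
    ``O = U Vᵀ`` — the symmetric or Löwdin orthogonalisation of ``Z``.

    Raises
    ------
    ShapeError
        If ``Z`` has fewer rows than columns.
    DegenerateInputError
        If the singular-value ratio ``σ_min/σ_max`` falls below the rank
        tolerance (1e-10), i.e. the columns are numerically dependent.
    """
    Z = _as_2d(Z)
    m, n = Z.shape
    if m < n:
        raise ShapeError(f"need at least as many samples as nodes, got {m} × {n}")
    U, s, Vt = scipy.linalg.svd(Z, full_matrices=False)
    ratio = s[-1] / s[0] if s[0] > 0 else 0.0
    if ratio < RANK_TOLERANCE:
        raise DegenerateInputError(
            f"rank-deficient input: singular-value ratio {ratio:.3e} "
            f"below tolerance {RANK_TOLERANCE:.0e}"
        )
    return U @ Vt


def reconstruction_error(Z, P) -> float:
    """Squared Frobenius distance ``trace((Z − P)ᵀ(Z − P))``."""
    Z = np.asarray(Z, dtype=float)
    P = np.asarray(P, dtype=float)
    if Z.shape != P.shape:
        raise ShapeError(f"shape mismatch: {Z.shape} vs {P.shape}")
    diff = Z - P
    return float(np.sum(diff * diff))


def symmetric_orthogonalise(
    Z,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> OrthogonalisedSet:
    """Closest set of mutually orthogonal vectors to the columns of ``Z``.

    Alternates, starting from ``D = I``:

    1. ``O ← closest_orthonormal(Z D)``  (optimal orientations given
       magnitudes);
    2. ``d ← diag(Zᵀ O)``  (optimal magnitudes given orientations),

    which monotonically decreases ``ε = ‖Z − O D‖²_F``.  Iteration stops
    when the change in ``ε`` relative to ``‖Z‖²_F`` falls below
    ``tolerance``.  Convergence is guaranteed, though not necessarily to
    the global minimum; in practice twenty iterations suffice.

    Parameters
    ----------
    Z : array-like, shape (m, n)
        Raw time-courses, samples × nodes, ``m ≥ n``, full column rank.
    tolerance : float
        Stop when ``|ε_k − ε_{k−1}| / ‖Z‖²_F`` falls below this.
    max_iterations : int
        Iteration cap; hitting it sets ``converged = False`` (no raise).

    Returns
    -------
    OrthogonalisedSet
    """
    Z = _as_2d(Z)
    m, n = Z.shape
    if m < n:
        raise ShapeError(f"need at least as many samples as nodes, got {m} × {n}")

    scale = float(np.sum(Z * Z))
    if scale == 0.0:
        raise DegenerateInputError("all-zero input")

    d = np.ones(n)
    prev_err = np.inf
    trace: list[float] = []
    converged = False
    iterations = 0
    O = np.empty_like(Z)

    for iterations in range(1, max_iterations + 1):
        O = closest_orthonormal(Z * d)  # Z @ diag(d), column scaling
        d = np.einsum("ij,ij->j", Z, O)  # diag(Z.T @ O)
        err = scale - float(np.sum(d * d))  # ε = ‖Z‖² − Σ dᵢ² at optimal d
        trace.append(err)
        if abs(prev_err - err) / scale < tolerance:
            converged = True
            break
        prev_err = err

    if converged and np.any(d <= 0):
        k = int(np.argmin(d))
        raise DegenerateInputError(
            f"non-positive magnitude d[{k}] = {d[k]:.3e} at convergence; "
            "a corrected vector collapsed onto the orthogonal complement of its input"
        )

    P = O * d
    return OrthogonalisedSet(
        P=P, O=O, d=d, error_trace=trace, iterations=iterations, converged=converged
    )


def pairwise_orthogonalise(x, y, tolerance: float = 1e-10):
    """Regress each of two time-courses from the other.

    Returns ``(y_res, x_res)`` where ``y_res`` is the residual of ``y``
    after projecting out ``x`` (so that ``x`` is the seed) and ``x_res``
    the residual of ``x`` after projecting out ``y``.  Each residual has
    zero inner product with its seed.  The two seed choices generally give
    different corrected pairs; downstream comparisons average over both.

    Raises
    ------
    DegenerateInputError
        If the inputs are collinear (``|corr| > 1 − tolerance``) or either
        is identically zero.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ShapeError("time-courses must share a length of at least 2")
    nx = float(np.dot(x, x))
    ny = float(np.dot(y, y))
    if nx == 0.0 or ny == 0.0:
        raise DegenerateInputError("cannot orthogonalise a zero time-course")
    c = float(np.dot(x, y)) / np.sqrt(nx * ny)
    if abs(c) > 1.0 - tolerance:
        raise DegenerateInputError(f"collinear pair: |cosine| = {abs(c):.12f}")
    y_res = y - (np.dot(x, y) / nx) * x
    x_res = x - (np.dot(y, x) / ny) * y
    return y_res, x_res
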