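"""Riemannian geometry primitives for symmetric positive definite matrices.

The SPD matrices of a fixed size form a manifold; under the affine-invariant
metric the tangent space at a base point ``S`` is the space of symmetric
matrices, reached by the logarithmic map

    Log_S(S_i) = S^{1/2} logm(S^{-1/2} S_i S^{-1/2}) S^{1/2}

and left by the exponential map

    Exp_S(T_i) = S^{1/2} expm(S^{-1/2} T_i S^{-1/2}) S^{1/2}.

The geodesic distance between two SPD matrices is the Frobenius norm of the
log-eigenvalues of ``S1^{-1/2} S2 S1^{-1/2}`` — invariant under congruence by
any invertible matrix.

All spectral functions use the eigendecomposition pattern ``U f(V) U^T`` on
the symmetrized input, in double precision. Eigenvalues below 1e-12 raise a
domain error rather than being clamped — clamping is the graph-construction
stage's job, and silent repair here would mask bugs.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

from .exceptions import NotSPDError, NumericalError

__all__ = [
    "is_spd",
    "sym",
    "matrix_log",
    "matrix_exp",
    "matrix_sqrt",
    "log_map",
    "exp_map",
    "geodesic_distance",
]

_EIG_FLOOR = 1e-12


def sym(M: np.ndarray) -> np.ndarray:
    """Exact symmetrization (M + M^T) / 2."""
    M = np.asarray(M, dtype=np.float64)
    return (M + M.swapaxes(-1, -2)) / 2.0


def _check_square(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise NotSPDError(f"expected a square matrix, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise NumericalError("matrix contains non-finite entries")
    return M


def is_spd(M: np.ndarray, tol: float = 1e-10) -> bool:
    """True iff M is symmetric within ``tol`` and has all eigenvalues > 0.

    Eigenvalues below the 1e-12 numerical floor count as zero, so an exactly
    singular matrix is not declared SPD by round-off.
    """
    M = _check_square(M)
    if np.max(np.abs(M - M.T)) > tol:
        return False
    return bool(np.linalg.eigvalsh(sym(M)).min() > _EIG_FLOOR)


def _spd_eig(S: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    S = _check_square(S)
    w, U = np.linalg.eigh(sym(S))
    if w.min() <= _EIG_FLOOR:
        raise NotSPDError(
            f"{what}: matrix is not positive definite (min eigenvalue {w.min():.3e})"
        )
    return w, U


def _spectral(S: np.ndarray, fn, what: str) -> np.ndarray:
    w, U = _spd_eig(S, what)
    return sym((U * fn(w)) @ U.T)


def matrix_log(S: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm of an SPD matrix (symmetric output)."""
    return _spectral(S, np.log, "matrix_log")


def matrix_sqrt(S: np.ndarray) -> np.ndarray:
    """SPD square root of an SPD matrix."""
    return _spectral(S, np.sqrt, "matrix_sqrt")


def _inv_sqrt(S: np.ndarray, what: str) -> np.ndarray:
    return _spectral(S, lambda w: 1.0 / np.sqrt(w), what)


def matrix_exp(T: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix; the output is SPD."""
    T = _check_square(T)
    w, U = np.linalg.eigh(sym(T))
    return sym((U * np.exp(w)) @ U.T)


def log_map(base: np.ndarray, S_i: np.ndarray) -> np.ndarray:
    """Project an SPD matrix to the tangent space at ``base`` (symmetric)."""
    half = matrix_sqrt(base)
    inv_half = _inv_sqrt(base, "log_map")
    inner = matrix_log(sym(inv_half @ sym(_check_square(S_i)) @ inv_half))
    return sym(half @ inner @ half)


def exp_map(base: np.ndarray, T_i: np.ndarray) -> np.ndarray:
    """Map a tangent vector at ``base`` back to the manifold; output is SPD."""
    half = matrix_sqrt(base)
    inv_half = _inv_sqrt(base, "exp_map")
    inner = matrix_exp(sym(inv_half @ sym(_check_square(T_i)) @ inv_half))
    return sym(half @ inner @ half)


def geodesic_distance(S1: np.ndarray, S2: np.ndarray) -> float:
    """Affine-invariant geodesic distance between two SPD matrices.

    Computed as ``sqrt(sum(log(lambda)^2))`` over the generalized eigenvalues
    of the pencil (S2, S1); zero iff S1 == S2, symmetric in its arguments.
    """
    _spd_eig(S1, "geodesic_distance")  # validate both inputs
    _spd_eig(S2, "geodesic_distance")
    w = sla.eigh(sym(S2), sym(S1), eigvals_only=True)
    if w.min() <= 0:
        raise NotSPDError("generalized eigenvalues not positive")
    return float(np.sqrt(np.sum(np.log(w) ** 2)))
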