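"""From connectivity matrices to SPD-rectified graph Laplacians.

A connectivity matrix becomes an undirected graph by magnitude thresholding:
off-diagonal entries with ``|value| >= threshold`` are kept as edge weights
(or as 1s in binary mode), everything else is dropped. The combinatorial
Laplacian ``L = D - A`` of that graph is symmetric positive *semi*-definite —
the constant vector is always in its null space — so its smallest eigenvalue
is clamped up to a floor ``epsilon`` by eigenvalue rectification,

    L_spd = U max(eps I, Sigma) U^T,

yielding a symmetric positive definite matrix that can live on the SPD
manifold and feed the SPD network.

Thresholds for PLV/PCC/COH are absolute values on the estimator's own scale.
MI has no universal scale (it depends on the binning), so MI thresholds are
interpreted as quantile levels of the matrix's off-diagonal distribution; a
nominal threshold ``t`` on a 0-0.65 reference scale maps to the ``t / 0.65``
quantile. Negative correlations are thresholded by magnitude: a strong
anticorrelation is as real an edge as a strong correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix, _check_kind
from .exceptions import ConfigError, DataError

__all__ = [
    "DEFAULT_THRESHOLDS",
    "AdjacencyGraph",
    "RectifiedLaplacian",
    "resolve_threshold",
    "threshold_to_adjacency",
    "laplacian",
    "rectify_spd",
    "spd_from_connectivity",
    "spd_stack",
]

# per-feature defaults: sweep optima on the reference protocol
DEFAULT_THRESHOLDS = {"plv": 0.6, "pcc": 0.7, "mi": 0.35, "coh": 0.4}

MI_REFERENCE_MAX = 0.65  # nominal top of the MI threshold scale


@dataclass
class AdjacencyGraph:
    """Non-negative symmetric adjacency with zero diagonal."""

    A: np.ndarray
    threshold: float
    kind: str | None = None
    binary: bool = False

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise DataError(f"adjacency must be square, got {self.A.shape}")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.A.sum(axis=1)


@dataclass
class RectifiedLaplacian:
    """SPD matrix obtained by eigenvalue-rectifying a graph Laplacian."""

    L: np.ndarray
    degrees: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    epsilon: float


def resolve_threshold(
    values: np.ndarray, kind: str | None, threshold: float | None
) -> float:
    """Absolute threshold for a matrix, honoring the MI quantile convention."""
    if threshold is None:
        if kind is None:
            raise ConfigError("either a threshold or a feature kind is required")
        threshold = DEFAULT_THRESHOLDS[_check_kind(kind)]
    if kind is not None and _check_kind(kind) == "mi":
        level = min(max(threshold / MI_REFERENCE_MAX, 0.0), 1.0)
        off = np.abs(values[~np.eye(values.shape[0], dtype=bool)])
        return float(np.quantile(off, level))
    return float(threshold)


def threshold_to_adjacency(
    conn: ConnectivityMatrix | np.ndarray,
    threshold: float | None = None,
    binary: bool = False,
    kind: str | None = None,
) -> AdjacencyGraph:
    """Magnitude-threshold a connectivity matrix into an undirected graph.

    Off-diagonal entries with ``|value| >= threshold`` become edges weighted
    by their magnitude (or by 1 in ``binary`` mode); the diagonal is ignored
    (no self-loops). Raising the threshold never adds an edge.
    """
    if isinstance(conn, ConnectivityMatrix):
        values, kind = conn.values, conn.kind
    else:
        values = np.asarray(conn, dtype=np.float64)
    thr = resolve_threshold(values, kind, threshold)
    mag = np.abs((values + values.T) / 2.0)
    A = np.where(mag >= thr, 1.0 if binary else mag, 0.0)
    np.fill_diagonal(A, 0.0)
    return AdjacencyGraph(A=A, threshold=thr, kind=kind, binary=binary)


def laplacian(graph: AdjacencyGraph | np.ndarray) -> np.ndarray:
    """Combinatorial Laplacian L = D - A; symmetric PSD, rows sum to zero."""
    A = graph.A if isinstance(graph, AdjacencyGraph) else np.asarray(graph, dtype=np.float64)
    A = (A + A.T) / 2.0
    return np.diag(A.sum(axis=1)) - A


def rectify_spd(L: np.ndarray, epsilon: float = 1e-4) -> RectifiedLaplacian:
    """Clamp eigenvalues below ``epsilon`` up to ``epsilon`` and reconstruct.

    The output is SPD with min eigenvalue >= epsilon; inputs whose spectrum
    already clears the floor are returned unchanged up to round-off.
    """
    if epsilon <= 0:
        raise ConfigError(f"epsilon must be positive, got {epsilon}")
    L = np.asarray(L, dtype=np.float64)
    if not np.all(np.isfinite(L)):
        raise DataError("Laplacian contains non-finite entries")
    Ls = (L + L.T) / 2.0
    w, U = np.linalg.eigh(Ls)
    wc = np.maximum(w, epsilon)
    out = (U * wc) @ U.T
    return RectifiedLaplacian(
        L=(out + out.T) / 2.0,
        degrees=np.diag(Ls).copy(),
        eigvals=wc,
        eigvecs=U,
        epsilon=epsilon,
    )


def spd_from_connectivity(
    conn: ConnectivityMatrix | np.ndarray,
    threshold: float | None = None,
    epsilon: float = 1e-4,
    binary: bool = False,
    kind: str | None = None,
) -> np.ndarray:
    """Connectivity matrix -> thresholded graph -> rectified Laplacian (SPD)."""
    graph = threshold_to_adjacency(conn, threshold=threshold, binary=binary, kind=kind)
    return rectify_spd(laplacian(graph), epsilon=epsilon).L


def spd_stack(
    conns: np.ndarray,
    kind: str | None = None,
    threshold: float | None = None,
    epsilon: float = 1e-4,
    binary: bool = False,
) -> np.ndarray:
    """Apply :func:`spd_from_connectivity` over a (n, C, C) stack."""
    conns = np.asarray(conns, dtype=np.float64)
    out = np.empty_like(conns)
    for i in range(conns.shape[0]):
        out[i] = spd_from_connectivity(
            conns[i], threshold=threshold, epsilon=epsilon, binary=binary, kind=kind
        )
    return out
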