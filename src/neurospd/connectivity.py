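"""Pairwise functional-connectivity estimators and per-epoch matrices.

Four estimators, each summarizing the dependence between two channel signals
as one scalar per unordered pair:

PLV
    phase locking value — magnitude of the time-averaged complex exponential
    of the instantaneous phase difference, ``|mean_t exp(j(phi_m - phi_n))|``.
    Phase comes from the analytic signal (Hilbert transform); 5% of samples
    at each edge are excluded from the average to limit transform edge
    artifacts. Range [0, 1].
PCC
    Pearson correlation coefficient in the time domain. Range [-1, 1].
COH
    magnitude-squared spectral coherence ``|P_mn(f)|^2 / (P_mm(f) P_nn(f))``
    from Welch cross-/auto-spectra, averaged over the 1-47 Hz band. The Welch
    segments are 0.5 s with 50% overlap and a Hann window — short epochs
    (1 s) leave room for nothing longer. Range [0, 1].
MI
    mutual information in bits from an equal-width 2-D histogram (16 bins per
    axis). Sensitive to nonlinear dependence the three linear/phase measures
    miss. Non-negative, unbounded above.

Each per-epoch matrix is symmetric; diagonals are 1 for PLV/PCC/COH and the
channel's self-information (binned entropy) for MI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigError, DataError
from .signals import EpochedSignals

__all__ = [
    "KINDS",
    "ConnectivityMatrix",
    "plv",
    "pcc",
    "coh",
    "mi",
    "mutual_information_from_joint",
    "connectivity_matrix",
    "connectivity_matrices",
]

KINDS = ("plv", "pcc", "coh", "mi")

PLV_EDGE_FRAC = 0.05


def _check_kind(kind: str) -> str:
    k = kind.lower()
    if k not in KINDS:
        raise ConfigError(f"unknown connectivity kind {kind!r}; choose from {KINDS}")
    return k


@dataclass
class ConnectivityMatrix:
    """C x C symmetric feature matrix tagged with its estimator kind."""

    values: np.ndarray
    kind: str
    epoch: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.kind = _check_kind(self.kind)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DataError(f"connectivity matrix must be square, got {self.values.shape}")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _as_pair(x_m: np.ndarray, x_n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x_m = np.asarray(x_m, dtype=np.float64).ravel()
    x_n = np.asarray(x_n, dtype=np.float64).ravel()
    if x_m.shape != x_n.shape:
        raise DataError(f"signal lengths differ: {x_m.size} vs {x_n.size}")
    if x_m.size < 2:
        raise DataError("need at least 2 samples")
    return x_m, x_n


def _phases(x: np.ndarray) -> np.ndarray:
    if np.ptp(x) == 0:
        raise DataError("constant signal: instantaneous phase undefined")
    return np.angle(sps.hilbert(x))


def _trim(T: int) -> slice:
    k = int(PLV_EDGE_FRAC * T)
    return slice(k, T - k)


def plv(x_m: np.ndarray, x_n: np.ndarray) -> float:
    """Phase locking value of two equal-length signals, in [0, 1]."""
    x_m, x_n = _as_pair(x_m, x_n)
    sl = _trim(x_m.size)
    dphi = _phases(x_m)[sl] - _phases(x_n)[sl]
    return float(np.abs(np.mean(np.exp(1j * dphi))))


def pcc(x_m: np.ndarray, x_n: np.ndarray) -> float:
    """Pearson correlation coefficient, in [-1, 1]."""
    x_m, x_n = _as_pair(x_m, x_n)
    dm, dn = x_m - x_m.mean(), x_n - x_n.mean()
    denom = np.sqrt(np.sum(dm**2) * np.sum(dn**2))
    if denom == 0:
        raise DataError("zero-variance signal: correlation undefined")
    return float(np.sum(dm * dn) / denom)


def _welch_nperseg(T: int, fs: float) -> int:
    return min(max(int(round(fs / 2)), 8), T)


def _coh_spectrum(
    x_m: np.ndarray, x_n: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    nps = _welch_nperseg(x_m.size, fs)
    kw = dict(fs=fs, window="hann", nperseg=nps, noverlap=nps // 2, detrend="constant")
    f, pmn = sps.csd(x_m, x_n, **kw)
    _, pmm = sps.welch(x_m, **kw)
    _, pnn = sps.welch(x_n, **kw)
    return f, pmn, pmm.real, pnn.real


def coh(
    x_m: np.ndarray,
    x_n: np.ndarray,
    fs: float,
    band: tuple[float, float] = (1.0, 47.0),
) -> float:
    """Band-averaged magnitude-squared coherence, in [0, 1]."""
    x_m, x_n = _as_pair(x_m, x_n)
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ConfigError(f"band {band} must lie within (0, {fs / 2}) Hz")
    f, pmn, pmm, pnn = _coh_spectrum(x_m, x_n, fs)
    sel = (f >= low) & (f <= high)
    if not np.any(sel):
        raise ConfigError(f"no Welch frequency falls inside band {band}")
    if np.any(pmm[sel] <= 0) or np.any(pnn[sel] <= 0):
        raise DataError("zero auto-spectrum inside band: coherence undefined")
    msc = np.abs(pmn[sel]) ** 2 / (pmm[sel] * pnn[sel])
    return float(np.mean(msc))


def _bin_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:  # constant signal: single occupied bin, MI contribution zero
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, n_bins + 1)


def mutual_information_from_joint(joint: np.ndarray) -> float:
    """MI in bits from a joint probability table (marginals are its sums)."""
    joint = np.asarray(joint, dtype=np.float64)
    if np.any(joint < 0) or not np.isclose(joint.sum(), 1.0):
        raise DataError("joint table must be non-negative and sum to 1")
    pm = joint.sum(axis=1, keepdims=True)
    pn = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = joint[mask] / (pm @ pn)[mask]
    return float(np.sum(joint[mask] * np.log2(ratio)))


def mi(x_m: np.ndarray, x_n: np.ndarray, n_bins: int = 16) -> float:
    """Histogram mutual information in bits (equal-width bins per signal)."""
    x_m, x_n = _as_pair(x_m, x_n)
    if n_bins < 2:
        raise ConfigError(f"n_bins must be >= 2, got {n_bins}")
    counts, _, _ = np.histogram2d(
        x_m, x_n, bins=[_bin_edges(x_m, n_bins), _bin_edges(x_n, n_bins)]
    )
    return mutual_information_from_joint(counts / counts.sum())


def _plv_matrix(X: np.ndarray) -> np.ndarray:
    C, T = X.shape
    if np.any(np.ptp(X, axis=1) == 0):
        bad = int(np.flatnonzero(np.ptp(X, axis=1) == 0)[0])
        raise DataError(f"channel {bad} is constant: phase undefined")
    phi = np.angle(sps.hilbert(X, axis=-1))[:, _trim(T)]
    Z = np.exp(1j * phi)
    M = np.abs(Z @ Z.conj().T) / Z.shape[1]
    np.fill_diagonal(M, 1.0)
    return np.minimum(M, 1.0)


def _pcc_matrix(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise DataError(f"channel {int(np.flatnonzero(sd == 0)[0])} has zero variance")
    M = np.corrcoef(X)
    np.fill_diagonal(M, 1.0)
    return np.clip(M, -1.0, 1.0)


def _coh_matrix(X: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    C, T = X.shape
    low, high = band
    nps = _welch_nperseg(T, fs)
    kw = dict(fs=fs, window="hann", nperseg=nps, noverlap=nps // 2, detrend="constant")
    f, pall = sps.csd(X[:, None, :], X[None, :, :], **kw)  # (C, C, F)
    sel = (f >= low) & (f <= high)
    auto = np.real(pall[np.arange(C), np.arange(C)][:, sel])  # (C, F)
    if np.any(auto <= 0):
        raise DataError("zero auto-spectrum inside band: coherence undefined")
    num = np.abs(pall[:, :, sel]) ** 2
    den = auto[:, None, :] * auto[None, :, :]
    M = np.mean(num / den, axis=-1)
    np.fill_diagonal(M, 1.0)
    return np.minimum(M, 1.0)


def _mi_matrix(X: np.ndarray, n_bins: int) -> np.ndarray:
    C = X.shape[0]
    M = np.zeros((C, C))
    for i in range(C):
        M[i, i] = mi(X[i], X[i], n_bins=n_bins)  # self-information of binned channel
        for j in range(i + 1, C):
            M[i, j] = M[j, i] = mi(X[i], X[j], n_bins=n_bins)
    return M


def connectivity_matrix(
    epoch: np.ndarray,
    kind: str,
    fs: float | None = None,
    band: tuple[float, float] = (1.0, 47.0),
    n_bins: int = 16,
    epoch_index: int | None = None,
) -> ConnectivityMatrix:
    """Symmetric C x C connectivity matrix of one epoch.

    ``fs`` is required for COH only. Errors from pairwise estimators carry the
    offending channel index.
    """
    kind = _check_kind(kind)
    X = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    if kind == "plv":
        M = _plv_matrix(X)
    elif kind == "pcc":
        M = _pcc_matrix(X)
    elif kind == "coh":
        if fs is None:
            raise ConfigError("coherence requires the sampling rate fs")
        M = _coh_matrix(X, fs, band)
    else:
        M = _mi_matrix(X, n_bins)
    M = (M + M.T) / 2.0  # exact symmetry
    return ConnectivityMatrix(values=M, kind=kind, epoch=epoch_index)


def connectivity_matrices(
    epochs: EpochedSignals,
    kind: str,
    band: tuple[float, float] = (1.0, 47.0),
    n_bins: int = 16,
) -> np.ndarray:
    """Per-epoch connectivity stack, shape (n_epochs, C, C)."""
    kind = _check_kind(kind)
    out = np.empty((epochs.n_epochs, epochs.n_channels, epochs.n_channels))
    for e in range(epochs.n_epochs):
        out[e] = connectivity_matrix(
            epochs.data[e], kind, fs=epochs.fs, band=band, n_bins=n_bins, epoch_index=e
        ).values
    return out
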