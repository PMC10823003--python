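"""Signal conditioning and the trial-wise train/test protocol.

The target protocol: band-pass 1-47 Hz with a 4th-order Butterworth filter,
downsample to 200 Hz, cut the final two minutes of each trial into 1-s
non-overlapping epochs, and split train/test by whole trials (first nine
trials train, remaining six test). Filtering is applied zero-phase
(forward-backward) because the downstream phase-locking estimator depends on
undistorted instantaneous phase; the effective filter order therefore doubles.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigError, DataError
from .signals import EpochedSignals

__all__ = ["bandpass_filter", "downsample", "segment_trial", "segment_epochs", "split_trials"]


def bandpass_filter(
    raw: np.ndarray,
    fs: float,
    low: float = 1.0,
    high: float = 47.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Parameters
    ----------
    raw : ndarray, (..., n_samples)
    fs : sampling rate in Hz
    low, high : pass-band edges in Hz; must satisfy 0 < low < high < fs/2
    order : Butterworth design order (applied forward and backward, so the
        magnitude response is the squared ``order``-pole response)
    """
    if not 0 < low < high:
        raise ConfigError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= fs / 2:
        raise ConfigError(f"high={high} Hz must be below Nyquist {fs / 2} Hz")
    raw = np.asarray(raw, dtype=np.float64)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, raw, axis=-1)


def downsample(raw: np.ndarray, fs_in: float, fs_out: float = 200.0) -> np.ndarray:
    """Anti-aliased resampling along the last axis by a rational factor.

    Uses polyphase filtering; the output length is ``ceil(n * fs_out / fs_in)``
    (the resample_poly convention). ``fs_out == fs_in`` is the identity.
    """
    if fs_out > fs_in:
        raise ConfigError(f"fs_out={fs_out} exceeds fs_in={fs_in}")
    raw = np.asarray(raw, dtype=np.float64)
    if fs_out == fs_in:
        return raw.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return sps.resample_poly(raw, frac.numerator, frac.denominator, axis=-1)


def segment_trial(
    trial: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    keep_tail_s: float = 120.0,
) -> np.ndarray:
    """Cut the final ``keep_tail_s`` seconds into non-overlapping windows.

    Returns an ``(n_epochs, n_channels, window)`` array with
    ``n_epochs = keep_tail_s / window_s``. Trials shorter than ``keep_tail_s``
    are an error: silent truncation would silently unbalance classes.
    """
    trial = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    n_tail = int(round(keep_tail_s * fs))
    win = int(round(window_s * fs))
    if win <= 0:
        raise ConfigError("window_s must be positive")
    if trial.shape[-1] < n_tail:
        raise DataError(
            f"trial has {trial.shape[-1]} samples ({trial.shape[-1] / fs:.1f} s) "
            f"but keep_tail_s={keep_tail_s} s requires {n_tail}"
        )
    tail = trial[:, trial.shape[-1] - n_tail :]
    n_epochs = n_tail // win
    tail = tail[:, : n_epochs * win]
    return tail.reshape(trial.shape[0], n_epochs, win).transpose(1, 0, 2)


def segment_epochs(
    trials: Sequence[np.ndarray],
    fs: float,
    labels: Sequence[int],
    window_s: float = 1.0,
    keep_tail_s: float = 120.0,
    trial_ids: Sequence[int] | None = None,
) -> EpochedSignals:
    """Segment a list of trials into one EpochedSignals collection."""
    if len(trials) != len(labels):
        raise DataError(f"{len(trials)} trials but {len(labels)} labels")
    if trial_ids is None:
        trial_ids = list(range(len(trials)))
    chunks, lab, tid = [], [], []
    for k, trial in enumerate(trials):
        try:
            ep = segment_trial(trial, fs, window_s=window_s, keep_tail_s=keep_tail_s)
        except DataError as exc:
            raise DataError(f"trial {trial_ids[k]}: {exc}") from exc
        chunks.append(ep)
        lab.extend([labels[k]] * ep.shape[0])
        tid.extend([trial_ids[k]] * ep.shape[0])
    return EpochedSignals(
        data=np.concatenate(chunks, axis=0),
        fs=fs,
        labels=np.asarray(lab),
        trial_id=np.asarray(tid),
    )


def split_trials(
    epochs: EpochedSignals,
    n_train_trials: int = 9,
    n_test_trials: int = 6,
) -> tuple[EpochedSignals, EpochedSignals]:
    """Trial-wise split: first ``n_train_trials`` (in recording order) train.

    No epoch of one trial ever appears in both sets; the returned trial-id
    sets are disjoint by construction.
    """
    order = epochs.trial_order()
    if len(order) < n_train_trials + n_test_trials:
        raise DataError(
            f"need {n_train_trials + n_test_trials} trials, found {len(order)}"
        )
    train_ids = set(order[:n_train_trials].tolist())
    test_ids = set(order[n_train_trials : n_train_trials + n_test_trials].tolist())
    train = epochs.select(np.isin(epochs.trial_id, list(train_ids)))
    test = epochs.select(np.isin(epochs.trial_id, list(test_ids)))
    return train, test


def load_edf(path: str) -> tuple[np.ndarray, float]:
    """Read a continuous multichannel recording from an EDF file.

    Returns ``(data, fs)`` with data shaped (n_channels, n_samples). Requires
    the optional ``mne`` dependency.
    """
    import mne  # local import: optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"])
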