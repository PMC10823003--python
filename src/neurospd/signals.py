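"""Epoched multichannel signal container.

An :class:`EpochedSignals` holds a stack of fixed-length epochs cut from
longer trials: ``data`` is ``(n_epochs, n_channels, n_samples)``, and every
epoch carries a class label and the identity of the trial it was cut from.
Train/test protocol operates on trials, never on epochs, so temporally
adjacent windows cannot straddle the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigError, DataError


@dataclass
class EpochedSignals:
    """Stack of equal-length epochs with per-epoch labels and trial identity.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Real-valued signals.
    fs : float
        Sampling rate in Hz.
    labels : ndarray of int, shape (n_epochs,)
        Class label per epoch.
    trial_id : ndarray of int, shape (n_epochs,)
        Identifier of the source trial per epoch.
    subject_id, session_id : str
        Optional provenance identifiers.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    trial_id: np.ndarray
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.trial_id = np.asarray(self.trial_id, dtype=np.int64)
        if self.data.ndim != 3:
            raise DataError(
                f"data must be (n_epochs, n_channels, n_samples), got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        n = self.data.shape[0]
        if self.labels.shape != (n,) or self.trial_id.shape != (n,):
            raise DataError(
                "labels and trial_id must align with epochs: "
                f"{self.labels.shape}, {self.trial_id.shape} vs {n} epochs"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def trial_order(self) -> np.ndarray:
        """Distinct trial ids in order of first appearance."""
        _, idx = np.unique(self.trial_id, return_index=True)
        return self.trial_id[np.sort(idx)]

    def select(self, mask: np.ndarray) -> "EpochedSignals":
        """Subset of epochs by boolean mask or index array."""
        return replace(
            self,
            data=self.data[mask],
            labels=self.labels[mask],
            trial_id=self.trial_id[mask],
        )

    def __len__(self) -> int:
        return self.n_epochs
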