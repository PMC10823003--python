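"""HDF5 containers for pipeline intermediates.

Three container layouts share one file format:

epochs      datasets ``signals`` (n, C, T), ``labels``, ``trial_id``;
            attrs ``fs``, ``seed``/``spec`` when synthetic.
features    datasets ``features`` (n, C, C), ``labels``, ``trial_id``;
            attr ``kind``.
spd         datasets ``spd`` (n, C, C), ``labels``, ``trial_id``;
            attrs ``kind``, ``threshold``, ``epsilon``, ``binary``.

Every writer stamps the package version and, when given, a config hash.
"""

from __future__ import annotations

import numpy as np
import h5py

from . import __version__
from .exceptions import DataError
from .signals import EpochedSignals


def _stamp(g: h5py.File, config_hash: str | None) -> None:
    g.attrs["neurospd_version"] = __version__
    if config_hash:
        g.attrs["config_hash"] = config_hash


def save_epochs(
    path: str,
    epochs: EpochedSignals,
    spec_json: str | None = None,
    config_hash: str | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("trial_id", data=epochs.trial_id)
        f.attrs["fs"] = epochs.fs
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["session_id"] = epochs.session_id
        if spec_json:
            f.attrs["spec"] = spec_json
        _stamp(f, config_hash)


def load_epochs(path: str) -> EpochedSignals:
    with h5py.File(path, "r") as f:
        if "signals" not in f:
            raise DataError(f"{path} is not an epochs container")
        return EpochedSignals(
            data=f["signals"][...],
            fs=float(f.attrs["fs"]),
            labels=f["labels"][...],
            trial_id=f["trial_id"][...],
            subject_id=str(f.attrs.get("subject_id", "")),
            session_id=str(f.attrs.get("session_id", "")),
        )


def save_features(
    path: str,
    features: np.ndarray,
    labels: np.ndarray,
    trial_id: np.ndarray,
    kind: str,
    config_hash: str | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=np.asarray(features))
        f.create_dataset("labels", data=np.asarray(labels))
        f.create_dataset("trial_id", data=np.asarray(trial_id))
        f.attrs["kind"] = kind
        _stamp(f, config_hash)


def load_features(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    with h5py.File(path, "r") as f:
        if "features" not in f:
            raise DataError(f"{path} is not a features container")
        return (
            f["features"][...],
            f["labels"][...],
            f["trial_id"][...],
            str(f.attrs["kind"]),
        )


def save_spd(
    path: str,
    spd: np.ndarray,
    labels: np.ndarray,
    trial_id: np.ndarray,
    kind: str,
    threshold: float,
    epsilon: float,
    binary: bool = False,
    config_hash: str | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("spd", data=np.asarray(spd))
        f.create_dataset("labels", data=np.asarray(labels))
        f.create_dataset("trial_id", data=np.asarray(trial_id))
        f.attrs["kind"] = kind
        f.attrs["threshold"] = threshold
        f.attrs["epsilon"] = epsilon
        f.attrs["binary"] = binary
        _stamp(f, config_hash)


def load_spd(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        if "spd" not in f:
            raise DataError(f"{path} is not an SPD container")
        meta = {
            "kind": str(f.attrs["kind"]),
            "threshold": float(f.attrs["threshold"]),
            "epsilon": float(f.attrs["epsilon"]),
            "binary": bool(f.attrs["binary"]),
        }
        return f["spd"][...], f["labels"][...], f["trial_id"][...], meta
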