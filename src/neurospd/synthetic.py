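"""Synthetic multichannel EEG with planted, class-conditional coupling.

Emulates the structure of a 62-channel, 200 Hz emotion-recognition recording:
epoched signals grouped into trials, three classes, and — crucially — class
identity carried only by *which channel pairs are coupled*, never by
per-channel power. Each coupled pair shares a source built from a narrow-band
oscillator plus a band-limited broadband component, so that phase-based (PLV),
time-domain linear (PCC), frequency-domain linear (COH) and information-
theoretic (MI) estimators all see structure. A configurable fraction of
coupled pairs passes the shared source through a squashing nonlinearity on one
endpoint, giving MI structure that the linear estimators under-report.

This is a statistical testbed, not a biophysical forward model: no volume
conduction, no 1/f background, no artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigError
from .signals import EpochedSignals

__all__ = ["SyntheticSpec", "default_coupling_graph", "planted_adjacency", "generate_dataset"]


def default_coupling_graph(
    n_channels: int, n_classes: int
) -> dict[int, tuple[tuple[int, int], ...]]:
    """Deterministic per-class coupling graphs on ``n_channels`` nodes.

    Each class gets one perfect matching from the round-robin (circle-method)
    one-factorization of the complete graph: class ``k`` pairs the fixed
    vertex ``C - 1`` with ``k`` and vertex ``(k + i) mod (C - 1)`` with
    ``(k - i) mod (C - 1)``. Matchings of distinct classes are edge-disjoint
    for ``n_classes <= C - 1``, and every channel sits in at most one pair
    per class — so each coupled pair carries the full coupling strength, and
    class identity is encoded purely in *which* pairs are coupled.

    Odd channel counts use the scheme on ``C + 1`` with the dummy vertex's
    pair dropped (one channel per class stays uncoupled).
    """
    if n_channels < 2:
        raise ConfigError("need at least 2 channels")
    n = n_channels if n_channels % 2 == 0 else n_channels + 1
    m = n - 1
    graphs: dict[int, tuple[tuple[int, int], ...]] = {}
    for k in range(n_classes):
        r = k % m
        raw = [(n - 1, r)]
        raw += [((r + i) % m, (r - i) % m) for i in range(1, n // 2)]
        pairs = [
            (min(a, b), max(a, b))
            for a, b in raw
            if a < n_channels and b < n_channels and a != b
        ]
        graphs[k] = tuple(sorted(set(pairs)))
    return graphs


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic dataset.

    Defaults mirror the recording protocol the package targets: 62 channels at
    200 Hz, 1-s epochs, 3 classes, 15 trials (5 per class) of 120 epochs each
    (two minutes of non-overlapping 1-s windows per trial).

    coupling_strength is the mixing weight ``a`` of the shared pair source:
    a coupled channel is ``a * shared + (1 - a) * private`` before noise.
    noise_sd is the standard deviation of additive white noise on top of the
    unit-variance mixed signal. nonlinear_fraction selects the leading
    fraction of each class's pair list whose second endpoint receives
    ``tanh(2 * shared)`` instead of the shared source itself.
    """

    n_channels: int = 62
    fs: float = 200.0
    epoch_len: float = 1.0
    n_classes: int = 3
    n_trials_per_class: int = 5
    epochs_per_trial: int = 120
    coupling_strength: float | Sequence[float] = 0.9
    coupling_graph: Mapping[int, Sequence[tuple[int, int]]] | None = None
    noise_sd: float = 0.1
    nonlinear_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigError(f"n_channels must be >= 2, got {self.n_channels}")
        if self.fs <= 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")
        if self.epoch_len <= 0:
            raise ConfigError("epoch_len must be positive")
        if self.n_classes < 1:
            raise ConfigError("n_classes must be >= 1")
        if self.n_trials_per_class < 1 or self.epochs_per_trial < 1:
            raise ConfigError("trial/epoch counts must be positive")
        for a in np.atleast_1d(np.asarray(self.coupling_strength, dtype=float)):
            if not 0.0 <= a <= 1.0:
                raise ConfigError(f"coupling_strength must be in [0, 1], got {a}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0.0 <= self.nonlinear_fraction <= 1.0:
            raise ConfigError("nonlinear_fraction must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len))

    def strength_for(self, class_id: int) -> float:
        a = np.atleast_1d(np.asarray(self.coupling_strength, dtype=float))
        return float(a[class_id % len(a)])

    def graph_for(self, class_id: int) -> tuple[tuple[int, int], ...]:
        if not 0 <= class_id < self.n_classes:
            raise KeyError(f"unknown class {class_id} (n_classes={self.n_classes})")
        if self.coupling_graph is None:
            return default_coupling_graph(self.n_channels, self.n_classes)[class_id]
        try:
            pairs = self.coupling_graph[class_id]
        except (KeyError, IndexError) as exc:
            raise KeyError(f"no coupling graph for class {class_id}") from exc
        out = []
        for i, j in pairs:
            if not (0 <= i < self.n_channels and 0 <= j < self.n_channels) or i == j:
                raise ConfigError(f"invalid channel pair ({i}, {j})")
            out.append((min(i, j), max(i, j)))
        return tuple(sorted(set(out)))

    def to_json(self) -> str:
        d = asdict(self)
        if d["coupling_graph"] is not None:
            d["coupling_graph"] = {
                str(k): [list(p) for p in v] for k, v in d["coupling_graph"].items()
            }
        if not np.isscalar(d["coupling_strength"]):
            d["coupling_strength"] = list(np.asarray(d["coupling_strength"], dtype=float))
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        if d.get("coupling_graph") is not None:
            d["coupling_graph"] = {
                int(k): tuple(tuple(p) for p in v) for k, v in d["coupling_graph"].items()
            }
        return cls(**d)


def planted_adjacency(spec: SyntheticSpec, class_id: int) -> np.ndarray:
    """Binary ground-truth adjacency for one class: symmetric, zero diagonal."""
    A = np.zeros((spec.n_channels, spec.n_channels))
    for i, j in spec.graph_for(class_id):
        A[i, j] = A[j, i] = 1.0
    return A


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance broadband noise band-limited to 1-47 Hz (zero-phase)."""
    sos = sps.butter(4, [1.0, min(47.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * n))[n : 2 * n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _pair_source(rng: np.random.Generator, t: np.ndarray, freq: float, fs: float) -> np.ndarray:
    """Shared source: narrow-band oscillation + broadband component, ~unit variance."""
    phi = rng.uniform(0.0, 2 * np.pi)
    narrow = np.sqrt(2.0) * np.cos(2 * np.pi * freq * t + phi)  # unit variance
    broad = _bandlimited_noise(rng, t.size, fs)
    return (narrow + broad) / np.sqrt(2.0)


def _private_source(rng: np.random.Generator, t: np.ndarray, fs: float) -> np.ndarray:
    freq = rng.uniform(4.0, 30.0)
    return _pair_source(rng, t, freq, fs)


def generate_dataset(spec: SyntheticSpec) -> EpochedSignals:
    """Generate epoched signals with planted class-conditional connectivity.

    Trials are laid out in interleaved class order (class 0, 1, 2, 0, 1, ...)
    so that a "first n trials" split keeps classes balanced, matching a
    stimulus schedule that alternates conditions. Identical spec (same seed)
    yields bit-identical output.
    """
    C, T = spec.n_channels, spec.n_samples
    t = np.arange(T) / spec.fs
    root = np.random.SeedSequence(spec.seed)
    # one substream per trial so trial content is independent of trial count order
    n_trials = spec.n_classes * spec.n_trials_per_class
    trial_seeds = root.spawn(n_trials + 1)
    freq_rng = np.random.default_rng(trial_seeds[-1])

    # per-class pair metadata: center frequency and nonlinear flag, fixed per dataset
    class_pairs: dict[int, tuple[tuple[int, int], ...]] = {}
    pair_freq: dict[int, np.ndarray] = {}
    n_nonlin: dict[int, int] = {}
    for k in range(spec.n_classes):
        pairs = spec.graph_for(k)
        class_pairs[k] = pairs
        pair_freq[k] = freq_rng.uniform(6.0, 30.0, size=len(pairs))
        n_nonlin[k] = int(round(spec.nonlinear_fraction * len(pairs)))

    data = np.empty((n_trials * spec.epochs_per_trial, C, T))
    labels = np.empty(n_trials * spec.epochs_per_trial, dtype=np.int64)
    trial_id = np.empty_like(labels)

    ep = 0
    for tr in range(n_trials):
        k = tr % spec.n_classes  # interleaved class schedule
        a = spec.strength_for(k)
        rng = np.random.default_rng(trial_seeds[tr])
        pairs, freqs = class_pairs[k], pair_freq[k]
        for _ in range(spec.epochs_per_trial):
            shared = np.zeros((C, T))
            counts = np.zeros(C)
            for p, (i, j) in enumerate(pairs):
                s = _pair_source(rng, t, freqs[p], spec.fs)
                shared[i] += s
                if p < n_nonlin[k]:
                    g = np.tanh(2.0 * s)
                    shared[j] += g / max(g.std(), 1e-12)
                else:
                    shared[j] += s
                counts[i] += 1
                counts[j] += 1
            x = np.empty((C, T))
            for c in range(C):
                priv = _private_source(rng, t, spec.fs)
                if counts[c] > 0:
                    sh = shared[c] / np.sqrt(counts[c])
                    x[c] = a * sh + (1.0 - a) * priv
                else:
                    x[c] = priv
            if spec.noise_sd > 0:
                x = x + spec.noise_sd * rng.standard_normal((C, T))
            data[ep] = x
            labels[ep] = k
            trial_id[ep] = tr
            ep += 1

    return EpochedSignals(
        data=data, fs=spec.fs, labels=labels, trial_id=trial_id, subject_id="synthetic"
    )
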