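"""Decision-level fusion, accuracy, feature-mode grid, threshold sweep.

One SPD network is trained per connectivity feature; at test time their
per-class probability vectors are averaged elementwise (decision-level
fusion) and the fused argmax is the prediction. Ties resolve to the lowest
class index. Feature modes are the non-empty subsets of {PLV, PCC, MI, COH}:
4 singles, 6 pairs, 4 triples and the full quadruple — 15 modes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .connectivity import KINDS, connectivity_matrices
from .exceptions import ConfigError, DataError
from .graph import DEFAULT_THRESHOLDS, spd_stack
from .signals import EpochedSignals
from .spdnet import DecisionOutput, SPDNet, TrainConfig

__all__ = [
    "ConfusionCounts",
    "ExperimentResult",
    "average_fusion",
    "accuracy",
    "confusion_counts",
    "enumerate_modes",
    "prepare_spd_features",
    "train_feature_model",
    "run_mode",
    "threshold_sweep",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts; accuracy = (TP + TN) / total."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise DataError("empty confusion table")
        return (self.TP + self.TN) / self.total


@dataclass
class ExperimentResult:
    """Accuracy of one feature mode over one or more runs/subjects."""

    mode: str
    accuracies: list[float]
    per_kind: dict[str, float] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.accuracies))


def average_fusion(outputs: list[DecisionOutput]) -> DecisionOutput:
    """Elementwise mean of probability vectors; argmax with lowest-index ties."""
    if not outputs:
        raise ConfigError("average_fusion needs at least one decision")
    sizes = {o.probs.shape for o in outputs}
    if len(sizes) > 1:
        raise DataError(f"mismatched class counts across decisions: {sizes}")
    probs = np.mean([o.probs for o in outputs], axis=0)
    kinds = sorted({o.kind for o in outputs if o.kind})
    return DecisionOutput(
        probs=probs,
        predicted=int(np.argmax(probs)),
        kind="+".join(kinds) if kinds else None,
    )


def accuracy(pred, truth) -> float:
    """Proportion of correct labels (binary: (TP+TN)/total)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise DataError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise DataError("empty label lists")
    return float(np.mean(pred == truth))


def confusion_counts(pred, truth, positive: int = 1) -> ConfusionCounts:
    """Binary confusion counts with ``positive`` as the positive class."""
    pred = np.asarray(pred) == positive
    truth = np.asarray(truth) == positive
    return ConfusionCounts(
        TP=int(np.sum(pred & truth)),
        TN=int(np.sum(~pred & ~truth)),
        FP=int(np.sum(pred & ~truth)),
        FN=int(np.sum(~pred & truth)),
    )


def enumerate_modes(kinds: tuple[str, ...] = KINDS) -> list[tuple[str, ...]]:
    """All non-empty feature subsets, smallest first (15 modes for 4 kinds)."""
    return [
        combo
        for r in range(1, len(kinds) + 1)
        for combo in itertools.combinations(kinds, r)
    ]


def prepare_spd_features(
    epochs: EpochedSignals,
    kinds: tuple[str, ...],
    thresholds: dict[str, float] | None = None,
    epsilon: float = 1e-4,
    binary: bool = False,
) -> dict[str, np.ndarray]:
    """Connectivity -> thresholded graph -> rectified Laplacian, per kind."""
    thresholds = thresholds or {}
    out = {}
    for kind in kinds:
        if kind not in KINDS:
            raise ConfigError(f"unknown feature kind {kind!r}")
        conns = connectivity_matrices(epochs, kind)
        out[kind] = spd_stack(
            conns,
            kind=kind,
            threshold=thresholds.get(kind, DEFAULT_THRESHOLDS[kind]),
            epsilon=epsilon,
            binary=binary,
        )
    return out


def train_feature_model(
    S_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
    kind: str | None = None,
    bimap_dims: tuple[int, ...] | None = None,
    n_classes: int | None = None,
) -> SPDNet:
    """Train one SPD network on one feature's SPD stack."""
    n_classes = n_classes or int(np.max(y_train)) + 1
    net = SPDNet(
        input_dim=S_train.shape[-1],
        bimap_dims=bimap_dims,
        n_classes=n_classes,
        dropout_p=config.dropout,
        seed=config.seed,
        kind=kind,
    )
    net.fit(S_train, y_train, config)
    return net


def run_mode(
    train_epochs: EpochedSignals,
    test_epochs: EpochedSignals,
    mode: tuple[str, ...],
    config: TrainConfig,
    thresholds: dict[str, float] | None = None,
    epsilon: float = 1e-4,
    bimap_dims: tuple[int, ...] | None = None,
) -> ExperimentResult:
    """Train one network per feature in ``mode`` and fuse test decisions.

    Training never sees test epochs: the two inputs must have disjoint
    trial-id sets, which is asserted up front.
    """
    if not mode:
        raise ConfigError("mode must contain at least one feature kind")
    for kind in mode:
        if kind not in KINDS:
            raise ConfigError(f"unknown feature kind {kind!r}")
    overlap = set(train_epochs.trial_id.tolist()) & set(test_epochs.trial_id.tolist())
    if overlap:
        raise DataError(f"train/test trial ids overlap: {sorted(overlap)}")

    feats_train = prepare_spd_features(train_epochs, mode, thresholds, epsilon)
    feats_test = prepare_spd_features(test_epochs, mode, thresholds, epsilon)
    y_train, y_test = train_epochs.labels, test_epochs.labels
    n_classes = int(max(y_train.max(), y_test.max())) + 1

    per_kind: dict[str, float] = {}
    prob_stack = []
    for kind in mode:
        net = train_feature_model(
            feats_train[kind], y_train, config,
            kind=kind, bimap_dims=bimap_dims, n_classes=n_classes,
        )
        probs = np.atleast_2d(net.predict_proba(feats_test[kind]))
        prob_stack.append(probs)
        per_kind[kind] = accuracy(np.argmax(probs, axis=1), y_test)

    fused = np.mean(prob_stack, axis=0)
    fused_pred = np.argmax(fused, axis=1)
    used = {
        k: (thresholds or {}).get(k, DEFAULT_THRESHOLDS[k]) for k in mode
    }
    return ExperimentResult(
        mode="+".join(mode),
        accuracies=[accuracy(fused_pred, y_test)],
        per_kind=per_kind,
        thresholds=used,
    )


DEFAULT_SWEEPS = {
    "plv": (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    "pcc": (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    "coh": (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    "mi": (0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6),
}


def threshold_sweep(
    train_epochs: EpochedSignals,
    test_epochs: EpochedSignals,
    kind: str,
    thresholds: tuple[float, ...] | None = None,
    config: TrainConfig | None = None,
    epsilon: float = 1e-4,
    bimap_dims: tuple[int, ...] | None = None,
) -> list[ExperimentResult]:
    """Accuracy of one feature across a threshold grid (same split and seed)."""
    if kind not in KINDS:
        raise ConfigError(f"unknown feature kind {kind!r}")
    thresholds = thresholds or DEFAULT_SWEEPS[kind]
    config = config or TrainConfig()
    results = []
    for thr in thresholds:
        res = run_mode(
            train_epochs, test_epochs, (kind,), config,
            thresholds={kind: thr}, epsilon=epsilon, bimap_dims=bimap_dims,
        )
        results.append(res)
    return results
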