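"""Run configuration: YAML round-trip, validation, seed substreams, hashing.

A :class:`RunConfig` describes one end-to-end run. All randomness flows from
a single global seed: each stage draws from a named substream derived with
``SeedSequence(seed).spawn``, so re-running a stored config reproduces every
artifact bit-for-bit on one thread.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .connectivity import KINDS
from .exceptions import ConfigError
from .graph import DEFAULT_THRESHOLDS
from .spdnet import TrainConfig
from .synthetic import SyntheticSpec

_STAGES = ("simulate", "train")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML."""

    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    kinds: tuple[str, ...] = KINDS
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    epsilon: float = 1e-4
    binary: bool = False
    n_train_trials: int = 9
    n_test_trials: int = 6
    train: TrainConfig = field(default_factory=TrainConfig)
    bimap_dims: tuple[int, ...] | None = None
    modes: tuple[tuple[str, ...], ...] = (("plv", "pcc", "coh"), KINDS)
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        self.kinds = tuple(k.lower() for k in self.kinds)
        for k in self.kinds:
            if k not in KINDS:
                raise ConfigError(f"unknown feature kind {k!r}; choose from {KINDS}")
        self.modes = tuple(tuple(m.lower() for m in mode) for mode in self.modes)
        for mode in self.modes:
            for k in mode:
                if k not in self.kinds:
                    raise ConfigError(f"mode {mode} uses kind {k!r} not in kinds {self.kinds}")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if self.n_train_trials < 1 or self.n_test_trials < 1:
            raise ConfigError("trial split counts must be positive")

    # ------------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = json.loads(self.synthetic.to_json())
        d["modes"] = [list(m) for m in self.modes]
        d["kinds"] = list(self.kinds)
        if d["bimap_dims"] is not None:
            d["bimap_dims"] = list(d["bimap_dims"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticSpec.from_json(json.dumps(d["synthetic"]))
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "modes" in d:
            d["modes"] = tuple(tuple(m) for m in d["modes"])
        if "kinds" in d:
            d["kinds"] = tuple(d["kinds"])
        if d.get("bimap_dims") is not None:
            d["bimap_dims"] = tuple(d["bimap_dims"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        try:
            return cls.from_dict(d)
        except TypeError as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    # ---------------------------------------------------------------- utilities

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream seed derived from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)
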