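"""SPD matrix network: BiMap / ReEig / LogEig layers with a dense head.

The network maps an SPD input matrix through K blocks of

    BiMap   S_k = W_k S_{k-1} W_k^T          (W_k has orthonormal rows)
    ReEig   S_k = U max(eps I, V) U^T        (eigenvalue rectification)

followed by one LogEig layer ``U log(V) U^T`` that flattens the manifold
representation into Euclidean space, then dropout, an affine map to class
logits, and softmax. The congruence ``W S W^T`` with a full-row-rank W keeps
the representation SPD while shrinking its dimension; ReEig restores strict
positive definiteness after round-off; LogEig is the tangent-space map at the
identity.

Everything is plain numpy with hand-derived backward passes. Gradients of the
spectral layers use the Daleckii-Krein form: for ``f(S) = U g(V) U^T`` and an
upstream symmetric gradient ``dOut``,

    dS = U ( G .* (U^T dOut U) ) U^T,
    G_ij = (g(v_i) - g(v_j)) / (v_i - v_j),   G_ii = g'(v_i),

with eigenvalue-difference denominators guarded at 1e-12. BiMap weights are
optimized on the Stiefel manifold of row-orthonormal matrices: Euclidean
gradients are projected to the tangent space and each SGD step is retracted
by a sign-fixed QR decomposition, so ``W_k W_k^T = I`` holds after every
update. Weight decay applies to the dense head only — the manifold constraint
already regularizes the BiMap weights.

Training is deterministic under a fixed config seed on a single thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DataError, NumericalError

__all__ = [
    "TrainConfig",
    "DecisionOutput",
    "SPDNet",
    "bimap_forward",
    "reeig_forward",
    "logeig_forward",
    "default_bimap_dims",
]

_GAP_TOL = 1e-6  # eigen-gap below which training inputs get deterministic jitter
_JITTER = 1e-9
_DENOM_GUARD = 1e-12


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference protocol)."""

    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 200
    weight_decay: float = 0.0001
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ConfigError("learning_rate, batch_size, max_epochs must be positive")
        if self.weight_decay < 0 or not 0 <= self.dropout < 1:
            raise ConfigError("weight_decay must be >= 0 and dropout in [0, 1)")


@dataclass
class DecisionOutput:
    """Per-class probabilities from one feature-specific model."""

    probs: np.ndarray
    predicted: int
    kind: str | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-8:
            raise DataError("probs must be a probability vector")


def default_bimap_dims(input_dim: int) -> tuple[int, ...]:
    """Default BiMap output-dimension chain.

    62-channel inputs use the reference four-layer chain (31, 20, 16, 12);
    other sizes get a two-layer chain (3d/4, d/2) suited to small benchmarks.
    """
    if input_dim == 62:
        return (31, 20, 16, 12)
    a = max(2, (3 * input_dim) // 4)
    b = max(2, input_dim // 2)
    if b >= a:
        b = max(2, a - 1)
    return (a, b)


def _sym(M: np.ndarray) -> np.ndarray:
    return (M + M.swapaxes(-1, -2)) / 2.0


def bimap_forward(S: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Bilinear mapping W S W^T (batched over leading axes of S)."""
    S = np.asarray(S, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if S.shape[-1] != W.shape[1]:
        raise ConfigError(
            f"dimension mismatch: S is {S.shape[-2:]}, W is {W.shape}"
        )
    return _sym(np.einsum("ai,...ij,bj->...ab", W, S, W))


def reeig_forward(S: np.ndarray, epsilon: float = 1e-4) -> np.ndarray:
    """Eigenvalue rectification: clamp eigenvalues from below at epsilon."""
    S = np.asarray(S, dtype=np.float64)
    if not np.all(np.isfinite(S)):
        raise NumericalError("non-finite input to ReEig")
    w, U = np.linalg.eigh(_sym(S))
    wc = np.maximum(w, epsilon)
    return _sym(np.einsum("...ik,...k,...jk->...ij", U, wc, U))


def logeig_forward(S: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (batched)."""
    S = np.asarray(S, dtype=np.float64)
    w, U = np.linalg.eigh(_sym(S))
    if np.any(w <= 0):
        raise DataError(f"LogEig input not positive definite (min eig {w.min():.3e})")
    return _sym(np.einsum("...ik,...k,...jk->...ij", U, np.log(w), U))


def _loewner(w: np.ndarray, g: np.ndarray, gp: np.ndarray) -> np.ndarray:
    """First divided-difference matrix of g at eigenvalues w, (n, d, d)."""
    dif = w[:, :, None] - w[:, None, :]
    gdif = g[:, :, None] - g[:, None, :]
    small = np.abs(dif) < _DENOM_GUARD
    G = gdif / np.where(small, 1.0, dif)
    return np.where(small, (gp[:, :, None] + gp[:, None, :]) / 2.0, G)


def _spectral_backward(U: np.ndarray, G: np.ndarray, dOut: np.ndarray) -> np.ndarray:
    inner = U.swapaxes(-1, -2) @ _sym(dOut) @ U
    return _sym(U @ (G * inner) @ U.swapaxes(-1, -2))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _orthonormal_rows(rng: np.random.Generator, d_out: int, d_in: int) -> np.ndarray:
    Q, R = np.linalg.qr(rng.standard_normal((d_in, d_out)))
    Q = Q * np.sign(np.diag(R))  # sign-fixed for reproducibility
    return Q.T


class SPDNet:
    """(BiMap -> ReEig) x K -> LogEig -> flatten -> dropout -> dense -> softmax.

    Parameters
    ----------
    input_dim : side length of the SPD input matrices.
    bimap_dims : output dimension of each BiMap layer, strictly decreasing;
        defaults via :func:`default_bimap_dims`.
    n_classes : number of output classes.
    reeig_eps : rectification floor of every ReEig layer.
    dropout_p : dropout probability on the flattened LogEig features.
    seed : initialization seed.
    """

    def __init__(
        self,
        input_dim: int,
        bimap_dims: tuple[int, ...] | None = None,
        n_classes: int = 3,
        reeig_eps: float = 1e-4,
        dropout_p: float = 0.2,
        seed: int = 0,
        kind: str | None = None,
    ) -> None:
        if bimap_dims is None:
            bimap_dims = default_bimap_dims(input_dim)
        dims = (input_dim, *bimap_dims)
        if any(b >= a for a, b in zip(dims, dims[1:])):
            raise ConfigError(f"BiMap dims must be strictly decreasing, got {dims}")
        if reeig_eps <= 0:
            raise ConfigError("reeig_eps must be positive")
        self.dims = dims
        self.n_classes = int(n_classes)
        self.reeig_eps = float(reeig_eps)
        self.dropout_p = float(dropout_p)
        self.kind = kind
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.W = [
            _orthonormal_rows(rng, dims[k + 1], dims[k]) for k in range(len(dims) - 1)
        ]
        d_last = dims[-1]
        self.fc_W = rng.normal(0.0, 1.0 / d_last, size=(n_classes, d_last * d_last))
        self.fc_b = np.zeros(n_classes)
        self.history: list[dict] = []

    # ------------------------------------------------------------------ forward

    @property
    def feature_dim(self) -> int:
        return self.dims[-1] * self.dims[-1]

    def _forward(
        self,
        S: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        S = np.asarray(S, dtype=np.float64)
        squeeze = S.ndim == 2
        if squeeze:
            S = S[None]
        if S.shape[-1] != self.dims[0]:
            raise ConfigError(f"expected {self.dims[0]}x{self.dims[0]} inputs, got {S.shape[-2:]}")
        blocks = []
        cur = S
        for k, W in enumerate(self.W):
            B = bimap_forward(cur, W)
            if training:
                B = self._jitter_degenerate(B)
            w, U = np.linalg.eigh(B)
            wc = np.maximum(w, self.reeig_eps)
            R = _sym(np.einsum("nik,nk,njk->nij", U, wc, U))
            blocks.append({"S_in": cur, "w": w, "U": U, "wc": wc})
            cur = R
        last = blocks[-1]
        M = _sym(np.einsum("nik,nk,njk->nij", last["U"], np.log(last["wc"]), last["U"]))
        x = M.reshape(M.shape[0], -1)
        mask = None
        if training and self.dropout_p > 0:
            if rng is None:
                raise ConfigError("training forward pass needs an rng for dropout")
            mask = (rng.random(x.shape) >= self.dropout_p) / (1.0 - self.dropout_p)
            x = x * mask
        logits = x @ self.fc_W.T + self.fc_b
        probs = _softmax(logits)
        return {
            "blocks": blocks,
            "x": x,
            "mask": mask,
            "logits": logits,
            "probs": probs,
            "squeeze": squeeze,
        }

    def _jitter_degenerate(self, B: np.ndarray) -> np.ndarray:
        """Deterministically perturb matrices with near-degenerate spectra.

        Eigen-gaps below 1e-6 make the spectral backward ill-conditioned; a
        1e-9 graded diagonal shift breaks exact ties without moving the loss
        measurably.
        """
        w = np.linalg.eigvalsh(B)
        gaps = np.diff(np.sort(w, axis=1), axis=1)
        bad = np.any(gaps < _GAP_TOL, axis=1)
        if np.any(bad):
            d = B.shape[-1]
            B = B.copy()
            B[bad] += _JITTER * np.diag(np.arange(1, d + 1) / d)
        return B

    def forward(self, S: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities, shape (n, n_classes) (or (n_classes,) for one matrix)."""
        cache = self._forward(S, training=training, rng=rng)
        probs = cache["probs"]
        return probs[0] if cache["squeeze"] else probs

    def predict_proba(self, S: np.ndarray) -> np.ndarray:
        return self.forward(S, training=False)

    def predict(self, S: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(self.predict_proba(S))
        return np.argmax(p, axis=1)

    def decide(self, S: np.ndarray) -> list[DecisionOutput]:
        p = np.atleast_2d(self.predict_proba(S))
        return [DecisionOutput(probs=pi, predicted=int(np.argmax(pi)), kind=self.kind) for pi in p]

    # ----------------------------------------------------------------- backward

    def loss(self, S: np.ndarray, y: np.ndarray, weight_decay: float = 0.0) -> float:
        cache = self._forward(S, training=False)
        return self._loss_from_cache(cache, np.asarray(y), weight_decay)

    def _loss_from_cache(self, cache: dict, y: np.ndarray, weight_decay: float) -> float:
        p = cache["probs"]
        n = p.shape[0]
        ce = -np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-300)))
        return float(ce + 0.5 * weight_decay * np.sum(self.fc_W**2))

    def loss_and_grads(
        self,
        S: np.ndarray,
        y: np.ndarray,
        weight_decay: float = 0.0,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[float, dict]:
        """Mean cross-entropy (+ head weight decay) and parameter gradients.

        Gradients for the BiMap weights are Euclidean; Stiefel projection
        happens at update time so that finite-difference checks can compare
        against these directly.
        """
        y = np.asarray(y, dtype=np.int64)
        cache = self._forward(S, training=training, rng=rng)
        loss = self._loss_from_cache(cache, y, weight_decay)
        n = cache["probs"].shape[0]

        dlogits = cache["probs"].copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        d_fc_W = dlogits.T @ cache["x"] + weight_decay * self.fc_W
        d_fc_b = dlogits.sum(axis=0)
        dx = dlogits @ self.fc_W
        if cache["mask"] is not None:
            dx = dx * cache["mask"]

        d_last = self.dims[-1]
        dM = dx.reshape(n, d_last, d_last)

        # LogEig backward (shares the eigenbasis of the final ReEig output)
        last = cache["blocks"][-1]
        G_log = _loewner(last["wc"], np.log(last["wc"]), 1.0 / last["wc"])
        dR = _spectral_backward(last["U"], G_log, dM)

        dW_list: list[np.ndarray] = [None] * len(self.W)  # type: ignore[list-item]
        for k in range(len(self.W) - 1, -1, -1):
            blk = cache["blocks"][k]
            grad_active = (blk["w"] > self.reeig_eps).astype(np.float64)
            G_re = _loewner(blk["w"], blk["wc"], grad_active)
            dB = _spectral_backward(blk["U"], G_re, dR)
            Wk, S_in = self.W[k], blk["S_in"]
            dW_list[k] = np.einsum("nab,bi,nij->aj", dB + dB.swapaxes(1, 2), Wk, S_in)
            dR = _sym(np.einsum("ia,nij,jb->nab", Wk, dB, Wk))  # -> grad wrt S_in

        return loss, {"W": dW_list, "fc_W": d_fc_W, "fc_b": d_fc_b}

    # ----------------------------------------------------------------- training

    @staticmethod
    def _stiefel_project(W: np.ndarray, G: np.ndarray) -> np.ndarray:
        """Project a Euclidean gradient to the tangent space at row-orthonormal W."""
        WGt = W @ G.T
        return G - ((WGt + WGt.T) / 2.0) @ W

    @staticmethod
    def _retract(W: np.ndarray) -> np.ndarray:
        """Sign-fixed QR retraction back to row-orthonormal matrices."""
        Q, R = np.linalg.qr(W.T)
        Q = Q * np.sign(np.diag(R))
        return Q.T

    def orthonormality_error(self) -> float:
        """max_k || W_k W_k^T - I ||_max — the manifold-constraint residual."""
        return max(
            float(np.max(np.abs(W @ W.T - np.eye(W.shape[0])))) for W in self.W
        )

    def fit(self, S: np.ndarray, y: np.ndarray, config: TrainConfig | None = None) -> list[dict]:
        """Train by manifold SGD; returns the per-epoch training log.

        Every training matrix must already be SPD — non-SPD examples abort
        before the first step, naming the offending index.
        """
        config = config or TrainConfig()
        S = np.asarray(S, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if S.ndim != 3 or S.shape[0] != y.shape[0]:
            raise DataError(f"expected (n, C, C) matrices aligned with labels, got {S.shape}")
        if S.shape[0] < config.batch_size:
            raise DataError(
                f"need at least batch_size={config.batch_size} examples, got {S.shape[0]}"
            )
        asym = np.max(np.abs(S - S.swapaxes(1, 2)), axis=(1, 2))
        mins = np.linalg.eigvalsh(_sym(S)).min(axis=1)
        bad = np.flatnonzero((asym > 1e-8) | (mins <= 0))
        if bad.size:
            raise DataError(f"training example {bad[0]} is not SPD (min eig {mins[bad[0]]:.3e})")

        rng = np.random.default_rng(config.seed)
        lr = config.learning_rate
        self.history = []
        n = S.shape[0]
        for epoch in range(config.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                loss, grads = self.loss_and_grads(
                    S[idx], y[idx], weight_decay=config.weight_decay,
                    training=True, rng=rng,
                )
                if not np.isfinite(loss):
                    raise NumericalError(f"non-finite loss at epoch {epoch}")
                losses.append(loss)
                self.fc_W -= lr * grads["fc_W"]
                self.fc_b -= lr * grads["fc_b"]
                for k, dW in enumerate(grads["W"]):
                    xi = self._stiefel_project(self.W[k], dW)
                    self.W[k] = self._retract(self.W[k] - lr * xi)
            train_acc = float(np.mean(self.predict(S) == y))
            self.history.append(
                {"epoch": epoch, "loss": float(np.mean(losses)), "train_acc": train_acc}
            )
        return self.history

    # -------------------------------------------------------------- persistence

    def save(self, path: str) -> None:
        """Serialize parameters and architecture to one .npz checkpoint."""
        arrays = {f"W{k}": W for k, W in enumerate(self.W)}
        np.savez(
            path,
            fc_W=self.fc_W,
            fc_b=self.fc_b,
            dims=np.asarray(self.dims),
            meta=np.asarray(
                [self.n_classes, self.reeig_eps, self.dropout_p, self.seed], dtype=np.float64
            ),
            kind=np.asarray(self.kind or ""),
            **arrays,
        )

    @classmethod
    def load(cls, path: str) -> "SPDNet":
        z = np.load(path, allow_pickle=False)
        dims = tuple(int(d) for d in z["dims"])
        n_classes, eps, p, seed = z["meta"]
        kind = str(z["kind"]) or None
        net = cls(
            dims[0], bimap_dims=dims[1:], n_classes=int(n_classes),
            reeig_eps=float(eps), dropout_p=float(p), seed=int(seed), kind=kind,
        )
        net.W = [z[f"W{k}"] for k in range(len(dims) - 1)]
        net.fc_W = z["fc_W"]
        net.fc_b = z["fc_b"]
        return net
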