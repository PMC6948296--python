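"""Moving time-window input construction and the one-hidden-layer MLP.

The classifier input for minute ``k`` is the concatenation of the normalized
features of ``w`` consecutive segments ``k-w+1 .. k`` (oldest first, current
segment last); ``w=1`` reduces exactly to a plain per-segment MLP.  The
hidden-layer width follows the Kolmogorov superposition sizing heuristic
``H = 2*M + 1`` for ``M`` inputs, the activation is relu, the two linear
outputs are trained against one-hot targets by mini-batch backpropagation on
the squared error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from apneatw.config import TrainConfig
from apneatw.features import FEATURE_NAMES, NormStats

__all__ = [
    "WindowedDataset",
    "MlpModel",
    "hidden_size",
    "build_windows",
    "init_model",
    "forward",
    "train",
    "predict_segments",
]


def hidden_size(m: int) -> int:
    """Kolmogorov superposition sizing: H = 2*M + 1 hidden nodes for M inputs."""
    return 2 * m + 1


@dataclass
class WindowedDataset:
    X: np.ndarray                     # (n_samples, w * n_features)
    y: np.ndarray                     # {0 normal, 1 apnea}, current segment's label
    index: list[tuple[str, int]]      # (record_id, minute_index) per row
    w: int                            # segments per input, current one included

    def __len__(self) -> int:
        return len(self.y)


def build_windows(
    features_by_recording: dict[str, dict],
    w: int,
) -> WindowedDataset:
    """Concatenate ``w`` consecutive segments per sample, never across recordings.

    ``features_by_recording`` maps record_id to a dict with keys ``X`` (the
    normalized (n_minutes, 18) matrix), ``valid`` (bool per minute), ``label``
    (int per minute; -1 when unlabelled) and optionally ``minute_index``.
    Samples exist for minute indices ``k >= w-1``; any window touching an
    invalid segment is dropped.
    """
    if w < 1:
        raise ValueError(f"window size must be >= 1, got {w}")
    rows, ys, index = [], [], []
    for rec_id, rec in features_by_recording.items():
        X = np.asarray(rec["X"], dtype=float)
        valid = np.asarray(rec["valid"], dtype=bool)
        label = np.asarray(rec["label"])
        minutes = np.asarray(rec.get("minute_index", np.arange(len(valid))))
        for k in range(w - 1, len(valid)):
            if not valid[k - w + 1 : k + 1].all():
                continue
            rows.append(X[k - w + 1 : k + 1].reshape(-1))
            ys.append(int(label[k]))
            index.append((rec_id, int(minutes[k])))
    n_feat = w * (X.shape[1] if rows else len(FEATURE_NAMES))
    Xm = np.vstack(rows) if rows else np.empty((0, n_feat))
    return WindowedDataset(X=Xm, y=np.asarray(ys, dtype=int), index=index, w=w)


@dataclass
class MlpModel:
    W1: np.ndarray                    # (M, H)
    b1: np.ndarray                    # (H,)
    W2: np.ndarray                    # (H, C); output order [normal, apnea]
    b2: np.ndarray                    # (C,)
    M: int
    H: int
    C: int = 2
    activation: str = "relu"
    w: int = 1
    norm_stats: NormStats | None = None
    train_config: TrainConfig = field(default_factory=TrainConfig)
    loss_trace: list[float] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        assert self.H == hidden_size(self.M), "hidden layer must have 2M+1 nodes"

    # -- serialization: plain JSON, bit-reproducible via float repr round-trip
    def save(self, path: str | Path) -> None:
        d = {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "M": self.M,
            "H": self.H,
            "C": self.C,
            "activation": self.activation,
            "w": self.w,
            "norm_stats": self.norm_stats.to_dict() if self.norm_stats else None,
            "train_config": self.train_config.__dict__,
            "loss_trace": self.loss_trace,
            "feature_names": self.feature_names,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path: str | Path) -> "MlpModel":
        d = json.loads(Path(path).read_text())
        return cls(
            W1=np.asarray(d["W1"]),
            b1=np.asarray(d["b1"]),
            W2=np.asarray(d["W2"]),
            b2=np.asarray(d["b2"]),
            M=d["M"],
            H=d["H"],
            C=d["C"],
            activation=d["activation"],
            w=d["w"],
            norm_stats=NormStats.from_dict(d["norm_stats"]) if d["norm_stats"] else None,
            train_config=TrainConfig(**d["train_config"]),
            loss_trace=d["loss_trace"],
            feature_names=d["feature_names"],
        )


def init_model(M: int, C: int = 2, seed: int = 0, w: int = 1) -> MlpModel:
    """Glorot-uniform weights (+-sqrt(6/(fan_in+fan_out))), zero biases, H=2M+1."""
    if M < 1:
        raise ValueError("M must be >= 1")
    H = hidden_size(M)
    rng = np.random.default_rng(seed)
    lim1 = np.sqrt(6.0 / (M + H))
    lim2 = np.sqrt(6.0 / (H + C))
    return MlpModel(
        W1=rng.uniform(-lim1, lim1, size=(M, H)),
        b1=np.zeros(H),
        W2=rng.uniform(-lim2, lim2, size=(H, C)),
        b2=np.zeros(C),
        M=M,
        H=H,
        C=C,
        w=w,
    )


def forward(model: MlpModel, X: np.ndarray) -> np.ndarray:
    """Linear outputs y_c = W2' relu(W1' x + b1) + b2, shape (n, C)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.M:
        raise ValueError(f"expected {model.M} input features, got {X.shape[1]}")
    v = np.maximum(X @ model.W1 + model.b1, 0.0)
    return v @ model.W2 + model.b2


def _loss(model: MlpModel, X: np.ndarray, T: np.ndarray) -> float:
    Y = forward(model, X)
    return float(np.mean(np.sum((T - Y) ** 2, axis=1)))


def train(
    model: MlpModel, data: WindowedDataset, config: TrainConfig | None = None
) -> MlpModel:
    """Mini-batch SGD with momentum on the squared error against one-hot targets.

    A seeded validation split (``val_fraction``) drives early stopping with
    the configured patience; the best-validation weights are restored.  The
    per-epoch training loss is recorded in ``model.loss_trace``.
    """
    config = config or TrainConfig()
    X, y = data.X, data.y
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    T = np.zeros((len(y), model.C))
    T[np.arange(len(y)), y] = 1.0

    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.val_fraction * len(X)))
    order = rng.permutation(len(X))
    use_val = n_val >= 2
    if use_val:
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if len(np.unique(y[tr_idx])) < 2:      # tiny sets: keep all for training
            use_val, tr_idx = False, order
    else:
        tr_idx = order
    Xtr, Ttr = X[tr_idx], T[tr_idx]

    params = [model.W1, model.b1, model.W2, model.b2]
    vel = [np.zeros_like(p) for p in params]
    best = None
    best_val = np.inf
    stale = 0
    model.train_config = config
    model.loss_trace = []

    for _epoch in range(config.epochs):
        perm = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), config.batch_size):
            b = perm[start : start + config.batch_size]
            xb, tb = Xtr[b], Ttr[b]
            # forward
            z1 = xb @ model.W1 + model.b1
            v = np.maximum(z1, 0.0)
            yb = v @ model.W2 + model.b2
            # backward: mean over the batch of the summed squared error
            dY = 2.0 * (yb - tb) / len(xb)
            gW2 = v.T @ dY
            gb2 = dY.sum(axis=0)
            dV = dY @ model.W2.T
            dZ = dV * (z1 > 0)
            gW1 = xb.T @ dZ
            gb1 = dZ.sum(axis=0)
            for p, vl, g in zip(params, vel, (gW1, gb1, gW2, gb2)):
                vl *= config.momentum
                vl -= config.lr * g
                p += vl
        model.loss_trace.append(_loss(model, Xtr, Ttr))
        if use_val:
            vloss = _loss(model, X[val_idx], T[val_idx])
            if vloss < best_val - 1e-12:
                best_val = vloss
                best = [p.copy() for p in params]
                stale = 0
            else:
                stale += 1
                if stale > config.patience:
                    break
    if use_val and best is not None:
        model.W1, model.b1, model.W2, model.b2 = best
    return model


def predict_segments(
    model: MlpModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row predicted labels and apnea scores.

    The score is ``y_apnea - y_normal``; the label is the argmax with ties
    resolved to normal.
    """
    Y = forward(model, X)
    scores = Y[:, 1] - Y[:, 0]
    labels = (scores > 0).astype(int)
    return labels, scores
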