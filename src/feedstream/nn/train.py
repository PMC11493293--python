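"""Training and inference for the stream classifiers.

Each stream is trained independently with softmax cross-entropy over the
three feeding-intensity classes using adaptive-moment gradient descent.
Training is deterministic for a fixed seed (numpy is the only source of
randomness). Checkpoints are ``.npz`` weight archives plus a JSON
structural summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from ..dataio import LABELS
from .layers import Adam, BatchNorm, Layer, Sequential, softmax, softmax_cross_entropy
from .resnet import NetworkError

__all__ = [
    "TrainConfig",
    "StreamPrediction",
    "train_stream",
    "predict_stream",
    "predict_proba",
    "save_model",
    "load_model_weights",
    "iter_layers",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; loss is cross-entropy over the three classes."""

    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise NetworkError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise NetworkError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise NetworkError("learning_rate must be > 0")


@dataclass
class StreamPrediction:
    """Normalized per-class scores from one stream, ordered (none, weak, strong)."""

    scores: np.ndarray
    classes: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.classes),):
            raise NetworkError(f"expected {len(self.classes)} scores, got {self.scores.shape}")
        if (self.scores < 0).any() or abs(self.scores.sum() - 1.0) > 1e-6:
            raise NetworkError("scores must be non-negative and sum to 1")

    @property
    def argmax_label(self) -> str:
        return self.classes[int(np.argmax(self.scores))]


def iter_layers(layer: Layer) -> Iterator[Layer]:
    """Depth-first walk over a model's layers (containers included)."""
    yield layer
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from iter_layers(sub)
    for attr in ("main", "shortcut"):
        sub = getattr(layer, attr, None)
        if isinstance(sub, Layer):
            yield from iter_layers(sub)


def _accuracy(model: Sequential, X: np.ndarray, y: np.ndarray, batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for start in range(0, len(X), batch_size):
        xb, yb = X[start : start + batch_size], y[start : start + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train_stream(
    model: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    X_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Train one stream classifier in place; return the per-epoch history.

    ``X`` is the stream's sample array (NCHW images or (N, 1, L) vectors),
    ``y`` integer class indices. Every class must appear at least once in
    the training data. The history has exactly ``config.epochs`` rows with
    train (and, when a validation set is given, validation) loss and
    accuracy.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(X) != len(y) or len(X) == 0:
        raise NetworkError("X and y must be non-empty and of equal length")
    present = set(int(c) for c in np.unique(y))
    if present != set(range(len(LABELS))):
        missing = [LABELS[i] for i in range(len(LABELS)) if i not in present]
        raise NetworkError(f"training data is missing class(es): {missing}")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(X))
        epoch_loss, correct = 0.0, 0
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(xb)
            correct += int((logits.argmax(axis=1) == yb).sum())
        row = {
            "epoch": epoch + 1,
            "train_loss": epoch_loss / len(X),
            "train_acc": correct / len(X),
        }
        if X_val is not None and len(X_val):
            row["val_loss"], row["val_acc"] = _accuracy(model, X_val, y_val, config.batch_size)
        rows.append(row)
    return pd.DataFrame(rows)


def predict_proba(model: Sequential, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Normalized class scores for a batch, (N, n_classes), order preserved."""
    X = np.asarray(X, dtype=np.float64)
    out = []
    for start in range(0, len(X), batch_size):
        logits = model.forward(X[start : start + batch_size], train=False)
        out.append(softmax(logits))
    return np.concatenate(out, axis=0)


def predict_stream(model: Sequential, x: np.ndarray) -> StreamPrediction:
    """Predict one sample (adds the batch axis) as a :class:`StreamPrediction`."""
    probs = predict_proba(model, np.asarray(x)[None])
    return StreamPrediction(scores=probs[0])


def _state_arrays(model: Sequential) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.params()):
        state[f"param_{i:04d}"] = p.value
    bn = [l for l in iter_layers(model) if isinstance(l, BatchNorm)]
    for i, layer in enumerate(bn):
        state[f"bn_mean_{i:04d}"] = layer.running_mean
        state[f"bn_var_{i:04d}"] = layer.running_var
    return state


def save_model(model: Sequential, path, summary: Optional[dict] = None) -> Path:
    """Write weights to ``<path>`` (npz) with a JSON summary alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **_state_arrays(model))
    if summary is not None:
        path.with_suffix(".json").write_text(json.dumps(summary, indent=2))
    return path


def load_model_weights(model: Sequential, path) -> Sequential:
    """Load weights saved by :func:`save_model` into a same-structure model."""
    with np.load(Path(path)) as data:
        params = model.params()
        for i, p in enumerate(params):
            p.value[...] = data[f"param_{i:04d}"]
        bn = [l for l in iter_layers(model) if isinstance(l, BatchNorm)]
        for i, layer in enumerate(bn):
            layer.running_mean[...] = data[f"bn_mean_{i:04d}"]
            layer.running_var[...] = data[f"bn_var_{i:04d}"]
    return model
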