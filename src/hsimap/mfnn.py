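"""Multilayer feedforward neural network for tissue-class labelling.

A plain sigmoid network trained by gradient descent on mean squared error
against one-hot targets — no softmax, no momentum, no regularization. The
default architecture is one hidden layer of 16 units; depth is
configurable via ``layer_sizes``. Training uses a stratified 80/20
train/test split and is fully deterministic given the config seed (the
seed governs the split, the weight initialization, and minibatch
shuffling).

The network labels either individual pixels or whole segmentation
clusters (majority prediction within each cluster).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = ["MFNNConfig", "MFNNModel", "mfnn_train", "mfnn_predict",
           "label_map_from_segments", "save_model", "load_model"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MFNNConfig:
    hidden_sizes: tuple = (16,)
    learning_rate: float = 0.5
    epochs: int = 200
    batch_size: int | None = None  # None = full batch
    weight_init_scale: float = 0.5
    seed: int = 0
    train_fraction: float = 0.80

    def validate(self) -> None:
        if len(self.hidden_sizes) < 1:
            raise ValueError("at least one hidden layer is required")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError(f"hidden sizes must be >= 1; got {self.hidden_sizes}")
        if not 0 < self.train_fraction < 1:
            raise ValueError(
                f"train_fraction must be in (0, 1); got {self.train_fraction}"
            )
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0; got {self.learning_rate}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1; got {self.epochs}")


@dataclass
class MFNNModel:
    weights: list            # per-layer (fan_in, fan_out) matrices
    biases: list             # per-layer (fan_out,) vectors
    classes: np.ndarray      # class values in one-hot column order
    loss_trace: list         # per-epoch MSE on the training split
    config: MFNNConfig
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]


def _forward(weights, biases, X):
    """Return activations per layer (input first, output last)."""
    acts = [X]
    for W, b in zip(weights, biases):
        acts.append(_sigmoid(acts[-1] @ W + b))
    return acts


def _backward(weights, biases, X, T):
    """MSE/sigmoid backprop; returns (loss, weight grads, bias grads)."""
    acts = _forward(weights, biases, X)
    out = acts[-1]
    n = X.shape[0]
    loss = float(np.mean((out - T) ** 2))
    # dL/d(out) for L = mean over samples AND outputs of squared error.
    delta = 2.0 * (out - T) / (n * T.shape[1]) * out * (1.0 - out)
    gw, gb = [], []
    for layer in range(len(weights) - 1, -1, -1):
        gw.append(acts[layer].T @ delta)
        gb.append(delta.sum(axis=0))
        if layer > 0:
            delta = (delta @ weights[layer].T) * acts[layer] * (1.0 - acts[layer])
    return loss, gw[::-1], gb[::-1]


def mfnn_train(features: np.ndarray, labels: np.ndarray,
               cfg: MFNNConfig | None = None,
               split: bool = True) -> MFNNModel:
    """Train the network on a stratified 80/20 split of (features, labels).

    ``split=False`` trains on all samples (used for toy problems where a
    held-out set is meaningless). Raises on single-class input and on a
    non-finite loss (with the epoch index).
    """
    cfg = cfg or MFNNConfig()
    cfg.validate()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(f"features {X.shape} and labels {y.shape} disagree")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires at least 2 classes")

    rng = np.random.default_rng(cfg.seed)
    if split:
        idx_train, idx_test = train_test_split(
            np.arange(y.size), train_size=cfg.train_fraction,
            stratify=y, random_state=cfg.seed % (2**32),
        )
    else:
        idx_train = np.arange(y.size)
        idx_test = np.array([], dtype=int)
    Xtr, ytr = X[idx_train], y[idx_train]

    onehot = (ytr[:, None] == classes[None, :]).astype(float)
    sizes = [X.shape[1], *cfg.hidden_sizes, classes.size]
    weights = [rng.normal(0.0, cfg.weight_init_scale, size=(a, b))
               for a, b in zip(sizes[:-1], sizes[1:])]
    biases = [np.zeros(b) for b in sizes[1:]]

    n = Xtr.shape[0]
    batch = n if cfg.batch_size is None else min(cfg.batch_size, n)
    loss_trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            sel = order[start:start + batch]
            loss, gw, gb = _backward(weights, biases, Xtr[sel], onehot[sel])
            epoch_loss += loss * sel.size
            for layer in range(len(weights)):
                weights[layer] -= cfg.learning_rate * gw[layer]
                biases[layer] -= cfg.learning_rate * gb[layer]
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        loss_trace.append(epoch_loss)

    return MFNNModel(weights=weights, biases=biases, classes=classes,
                     loss_trace=loss_trace, config=cfg,
                     train_indices=idx_train, test_indices=idx_test)


def mfnn_predict(model: MFNNModel, features: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Predict class labels and per-class sigmoid scores.

    Ties in the output activations go to the lowest class index.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_inputs:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else '?'} does not "
            f"match model input width {model.n_inputs}"
        )
    scores = _forward(model.weights, model.biases, X)[-1]
    labels = model.classes[np.argmax(scores, axis=1)]  # argmax -> lowest on tie
    return labels, scores


def label_map_from_segments(seg, model: MFNNModel, features: np.ndarray,
                            shape: tuple[int, int],
                            per_pixel: bool = False) -> np.ndarray:
    """Assign a tissue class to every pixel via the trained network.

    Default mode gives each segmentation cluster the majority network
    prediction over its member pixels (ties -> lowest class); ``per_pixel``
    labels pixels independently instead.
    """
    preds, _ = mfnn_predict(model, features)
    labels = np.asarray(seg.labels).ravel()
    if per_pixel:
        return preds.reshape(shape)
    out = np.empty_like(preds)
    for c in np.unique(labels):
        members = labels == c
        if not members.any():
            raise ValueError(f"cluster {c} has no member pixels")
        values, counts = np.unique(preds[members], return_counts=True)
        out[members] = values[np.argmax(counts)]
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: MFNNModel, path: Path | str) -> Path:
    """Serialize to a portable ``.npz`` + JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {"classes": model.classes}
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez_compressed(path, **arrays)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = {"n_layers": len(model.weights),
            "loss_trace": model.loss_trace,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in model.config.__dict__.items()}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_model(path: Path | str) -> MFNNModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = dict(meta["config"])
    cfg_dict["hidden_sizes"] = tuple(cfg_dict["hidden_sizes"])
    cfg = MFNNConfig(**cfg_dict)
    with np.load(path) as npz:
        n = meta["n_layers"]
        weights = [npz[f"W{i}"] for i in range(n)]
        biases = [npz[f"b{i}"] for i in range(n)]
        classes = npz["classes"]
    return MFNNModel(weights=weights, biases=biases, classes=classes,
                     loss_trace=meta["loss_trace"], config=cfg)
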