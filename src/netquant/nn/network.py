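"""Sequential network container, losses, SGD-with-momentum and training loop.

Training follows the classical recipe used throughout the package: minibatch
stochastic gradient descent with momentum and a per-update multiplicative
learning-rate decay eta_t = eta0 / (1 + decay * t). Classification heads are
trained on logits with categorical cross-entropy (the softmax is folded into
the loss gradient); the counting head is trained with mean absolute error on
its rectified outputs. Everything is seeded: weight init, shuffling and
dropout all draw from generators derived from the configured seed, so a
fixed seed reproduces the training trajectory bit-for-bit in a fixed
environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layers import (AvgPool2, Conv2D, Dense, DenseBlock, Dropout, Flatten,
                     GlobalAvgPool, Layer, MaxPool2, ReLU)

__all__ = ["Sequential", "TrainConfig", "SGD", "train", "TrainingDiverged",
           "softmax", "save_model", "load_model"]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Sequential:
    """A plain stack of layers with an output-head convention.

    ``head`` names how raw outputs become predictions: ``"softmax"`` for
    classifiers (class probabilities) or ``"linear"`` for regression heads
    whose final activation, if any, is part of the layer stack itself.
    """

    def __init__(self, layers: list[Layer], head: str = "softmax",
                 name: str = "net"):
        if head not in ("softmax", "linear"):
            raise ValueError(f"unknown head {head!r}")
        self.layers = layers
        self.head = head
        self.name = name

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Raw head input (logits for softmax heads)."""
        self._acts = [x] if not train else None
        for layer in self.layers:
            x = layer.forward(x, train=train)
            if self._acts is not None:
                self._acts.append(x)
        return x

    def backward(self, dout: np.ndarray, guided: bool = False,
                 upto: int = 0, need_input_grad: bool = True) -> np.ndarray:
        """Backpropagate ``dout``; returns the gradient at layer ``upto``'s
        input (0 = the network input). With ``need_input_grad=False`` the
        bottom convolution skips its (unused) input-gradient product."""
        from .layers import Conv2D as _Conv
        stack = self.layers[upto:]
        for i, layer in list(enumerate(stack))[::-1]:
            if i == 0 and not need_input_grad and isinstance(layer, _Conv):
                layer.backward(dout, guided=guided, compute_dx=False)
                return None
            dout = layer.backward(dout, guided=guided)
        return dout

    # -- inference ----------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        outs = [self.forward(np.asarray(x[i:i + batch], dtype=np.float32))
                for i in range(0, len(x), batch)]
        z = np.concatenate(outs, axis=0)
        return softmax(z) if self.head == "softmax" else z

    def predict(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        p = self.predict_proba(x, batch=batch)
        return p.argmax(axis=-1) if self.head == "softmax" else p

    # -- bookkeeping --------------------------------------------------------
    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def set_rng(self, rng: np.random.Generator):
        for layer in self.layers:
            layer.set_rng(rng)

    def last_conv_index(self) -> int:
        idx = [i for i, l in enumerate(self.layers) if isinstance(l, Conv2D)]
        if not idx:
            raise ValueError("network has no convolutional layer")
        return idx[-1]


@dataclass
class TrainConfig:
    """Optimisation hyperparameters shared by all four networks.

    ``lr_step`` subtracts ``amount`` from the learning rate every
    ``every_n`` epochs (the schedule used by the object-level classifier);
    ``decay`` is the per-update multiplicative decay. ``early_stop`` watches
    the validation loss and stops once it has failed to improve for
    ``patience`` consecutive epochs.
    """

    loss: str = "categorical_cross_entropy"
    learning_rate: float = 1e-3
    decay: float = 1e-7
    momentum: float = 0.9
    epochs: int = 30
    batch_size: int = 32
    lr_step: tuple[float, int] | None = None
    early_stop: bool = False
    patience: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 and self.learning_rate != 0:
            raise ValueError("learning rate must be >= 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("categorical_cross_entropy", "mean_absolute_error"):
            raise ValueError(f"unknown loss {self.loss!r}")


class SGD:
    """Momentum SGD with per-update learning-rate decay."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 momentum: float = 0.9, decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.decay = decay
        self.t = 0
        self.vel = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        for p, g, v in zip(self.params, grads, self.vel):
            v *= self.momentum
            v -= lr_t * g
            p += v


def _ce_loss_grad(logits: np.ndarray, y: np.ndarray):
    p = softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    d = p
    d[np.arange(n), y] -= 1.0
    return float(loss), (d / n).astype(np.float32)


def _mae_loss_grad(pred: np.ndarray, y: np.ndarray):
    r = pred - y
    loss = float(np.abs(r).mean())
    return loss, (np.sign(r) / r.size).astype(np.float32)


def _eval_loss(model: Sequential, x, y, loss: str, batch: int = 256) -> float:
    tot, n = 0.0, 0
    for i in range(0, len(x), batch):
        out = model.forward(np.asarray(x[i:i + batch], dtype=np.float32))
        yb = y[i:i + batch]
        if loss == "categorical_cross_entropy":
            l, _ = _ce_loss_grad(out, yb)
        else:
            l, _ = _mae_loss_grad(out, yb)
        tot += l * len(yb)
        n += len(yb)
    return tot / max(n, 1)


def train(model: Sequential, x: np.ndarray, y: np.ndarray,
          config: TrainConfig,
          x_val: np.ndarray | None = None,
          y_val: np.ndarray | None = None) -> pd.DataFrame:
    """Train ``model`` in place; returns the per-epoch history.

    ``x`` must already be normalised/scaled; classification targets are
    integer class indices, regression targets are float arrays matching the
    head shape. Only ever call this on a training split (splitting and
    leakage guards live in :mod:`netquant.patches`).
    """
    if len(x) == 0:
        raise ValueError("empty training set")
    x = np.asarray(x, dtype=np.float32)
    rng = np.random.default_rng(config.seed)
    model.set_rng(np.random.default_rng(rng.integers(2**31)))
    loss_grad = (_ce_loss_grad if config.loss == "categorical_cross_entropy"
                 else _mae_loss_grad)
    opt = SGD(model.params(), config.learning_rate, config.momentum,
              config.decay)
    history = []
    best_val, since_best = np.inf, 0
    bs = config.batch_size
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        tot, seen = 0.0, 0
        for i in range(0, len(order), bs):
            idx = order[i:i + bs]
            out = model.forward(x[idx], train=True)
            loss, d = loss_grad(out, y[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss {loss} at epoch {epoch}, batch {i // bs}")
            model.backward(d, need_input_grad=False)
            opt.step(model.grads())
            tot += loss * len(idx)
            seen += len(idx)
        row = {"epoch": epoch, "train_loss": tot / seen, "lr": opt.lr}
        if x_val is not None and len(x_val):
            row["val_loss"] = _eval_loss(model, x_val, y_val, config.loss)
        history.append(row)
        if config.lr_step is not None:
            amount, every = config.lr_step
            if (epoch + 1) % every == 0:
                opt.lr = max(opt.lr - amount, 1e-12)
        if config.early_stop and "val_loss" in row:
            if row["val_loss"] < best_val - 1e-9:
                best_val, since_best = row["val_loss"], 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    return pd.DataFrame(history)


# -- (de)serialisation ------------------------------------------------------

_LAYER_TAGS = {
    Conv2D: "conv", Dense: "dense", ReLU: "relu", MaxPool2: "maxpool2",
    AvgPool2: "avgpool2", GlobalAvgPool: "gap", Dropout: "dropout",
    Flatten: "flatten", DenseBlock: "dense_block",
}


def save_model(model: Sequential, path: str) -> None:
    """Write weights (npz) plus an architecture JSON next to it.

    ``path`` should end in ``.npz``; the JSON sidecar is ``path + ".json"``.
    """
    if not str(path).endswith(".npz"):
        raise ValueError("model path must end in .npz")
    arch, arrays = [], {}
    for i, layer in enumerate(model.layers):
        tag = _LAYER_TAGS.get(type(layer))
        if tag is None:
            raise ValueError(f"cannot serialise layer {type(layer).__name__}")
        entry: dict = {"type": tag}
        if isinstance(layer, Conv2D):
            entry.update(c_in=layer.c_in, c_out=layer.c_out, k=layer.k)
            arrays[f"W{i}"], arrays[f"b{i}"] = layer.W, layer.b
        elif isinstance(layer, Dense):
            entry.update(d_in=layer.W.shape[0], d_out=layer.W.shape[1])
            arrays[f"W{i}"], arrays[f"b{i}"] = layer.W, layer.b
        elif isinstance(layer, DenseBlock):
            entry.update(c_in=layer.c_in, n_layers=layer.n_layers,
                         growth=layer.growth)
            for j, conv in enumerate(layer.convs):
                arrays[f"W{i}_{j}"], arrays[f"b{i}_{j}"] = conv.W, conv.b
        elif isinstance(layer, Dropout):
            entry["p"] = layer.p
        arch.append(entry)
    np.savez(path, **arrays)
    meta = {"name": model.name, "head": model.head, "layers": arch}
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(path: str) -> Sequential:
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    data = np.load(path)
    layers: list[Layer] = []
    for i, entry in enumerate(meta["layers"]):
        t = entry["type"]
        if t == "conv":
            layer = Conv2D(entry["c_in"], entry["c_out"], entry["k"])
            layer.W, layer.b = data[f"W{i}"], data[f"b{i}"]
            layer.dW, layer.db = np.zeros_like(layer.W), np.zeros_like(layer.b)
        elif t == "dense":
            layer = Dense(entry["d_in"], entry["d_out"])
            layer.W, layer.b = data[f"W{i}"], data[f"b{i}"]
            layer.dW, layer.db = np.zeros_like(layer.W), np.zeros_like(layer.b)
        elif t == "relu":
            layer = ReLU()
        elif t == "maxpool2":
            layer = MaxPool2()
        elif t == "avgpool2":
            layer = AvgPool2()
        elif t == "gap":
            layer = GlobalAvgPool()
        elif t == "dense_block":
            layer = DenseBlock(entry["c_in"], entry["n_layers"],
                               entry["growth"])
            for j, conv in enumerate(layer.convs):
                conv.W, conv.b = data[f"W{i}_{j}"], data[f"b{i}_{j}"]
                conv.dW = np.zeros_like(conv.W)
                conv.db = np.zeros_like(conv.b)
        elif t == "dropout":
            layer = Dropout(entry["p"])
        elif t == "flatten":
            layer = Flatten()
        else:
            raise ValueError(f"unknown layer tag {t!r}")
        layers.append(layer)
    return Sequential(layers, head=meta["head"], name=meta["name"])
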