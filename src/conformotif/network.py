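"""Block-structured 1D convolutional classifier, implemented on NumPy.

The architecture is a ladder of blocks, each ``Conv1d(kernel 3, stride 1,
no padding) → ReLU → MaxPool1d(window 2)``, with channel counts growing
64→128→256→512 in the default receptor-scale network, followed by a flatten,
a 1024-unit fully connected layer with ReLU and 0.5 dropout, and a 3-class
output layer.  Training uses cross-entropy with Adam (lr 1e-4, L2 weight
decay 1e-5), mini-batches of 1024 over 500 epochs, and Kaiming-uniform
initialization — the protocol used for the receptor study; reduced settings
are passed explicitly for small synthetic systems.

Everything a relevance engine needs — per-layer weights, biases, and the
activations entering each layer — is exposed directly; there is no opaque
graph.  Class order is fixed as (active=0, intermediate=1, inactive=2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .labeling import STATES


class NetworkError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Architecture arithmetic
# ---------------------------------------------------------------------------

def conv_output_length(length: int, kernel: int, stride: int = 1,
                       padding: int = 0) -> int:
    """Output length of a 1-D convolution: floor((L + 2p − k)/s) + 1."""
    if length + 2 * padding < kernel:
        raise NetworkError(
            f"convolution over length {length} with kernel {kernel} and padding "
            f"{padding} is degenerate; adding more blocks would lose the signal"
        )
    return (length + 2 * padding - kernel) // stride + 1


def pool_output_length(length: int, window: int) -> int:
    """Output length of non-overlapping max pooling: floor(L / window)."""
    if length < window:
        raise NetworkError(f"cannot pool length {length} with window {window}")
    return length // window


@dataclass(frozen=True)
class NetworkSpec:
    """Shape description of the block-structured classifier."""

    input_length: int = 846
    blocks: tuple[int, ...] = (64, 128, 256, 512)
    kernel: int = 3
    stride: int = 1
    padding: int = 0
    pool_window: int = 2
    fc_sizes: tuple[int, ...] = (1024, 3)
    dropout: float = 0.5

    @property
    def n_classes(self) -> int:
        return self.fc_sizes[-1]

    def block_lengths(self) -> list[tuple[int, int]]:
        """(post-conv, post-pool) lengths per block; raises on degenerate specs."""
        lengths = []
        length = self.input_length
        for _ in self.blocks:
            length = conv_output_length(length, self.kernel, self.stride, self.padding)
            conv_len = length
            length = pool_output_length(length, self.pool_window)
            lengths.append((conv_len, length))
        return lengths

    @property
    def flatten_length(self) -> int:
        """Channels × length entering the first fully connected layer."""
        if not self.blocks:
            return self.input_length
        return self.blocks[-1] * self.block_lengths()[-1][1]


def layer_summary(spec: NetworkSpec) -> list[dict]:
    """Architecture-summary rows: layer type, output shape, parameter count.

    Shapes and counts are derived from the NetworkSpec alone (no network is built);
    a forward pass through the built network is checked to agree in tests.
    """
    rows: list[dict] = []
    in_channels = 1
    lengths = spec.block_lengths()
    for b, out_channels in enumerate(spec.blocks):
        conv_len, pool_len = lengths[b]
        n_params = out_channels * (in_channels * spec.kernel) + out_channels
        rows.append({"layer": f"Conv1d-{b + 1}", "shape": (out_channels, conv_len),
                     "params": n_params})
        rows.append({"layer": f"ReLU-{b + 1}", "shape": (out_channels, conv_len),
                     "params": 0})
        rows.append({"layer": f"MaxPool1d-{b + 1}", "shape": (out_channels, pool_len),
                     "params": 0})
        in_channels = out_channels
    n_in = spec.flatten_length
    rows.append({"layer": "Flatten", "shape": (n_in,), "params": 0})
    for i, n_out in enumerate(spec.fc_sizes):
        rows.append({"layer": f"Linear-{i + 1}", "shape": (n_out,),
                     "params": n_out * n_in + n_out})
        if i < len(spec.fc_sizes) - 1:
            rows.append({"layer": f"ReLU-fc{i + 1}", "shape": (n_out,), "params": 0})
            if spec.dropout > 0:
                rows.append({"layer": "Dropout", "shape": (n_out,), "params": 0})
        n_in = n_out
    return rows


def parameter_count(spec: NetworkSpec) -> tuple[dict[str, int], int]:
    """Per-parametric-layer trainable-scalar counts and their total."""
    per_layer = {r["layer"]: r["params"] for r in layer_summary(spec) if r["params"]}
    return per_layer, sum(per_layer.values())


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: forward caches what backward/LRP need."""

    trainable: bool = False

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    trainable = True

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, bias: bool = True):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.W = np.zeros((out_channels, in_channels, kernel))
        self.b = np.zeros(out_channels) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._x: Optional[np.ndarray] = None

    def forward(self, x, training=False, rng=None):
        # x: (N, C_in, L)
        if x.shape[1] != self.in_channels:
            raise NetworkError(
                f"conv expected {self.in_channels} channels, got {x.shape[1]}"
            )
        self._x = x
        l_out = conv_output_length(x.shape[2], self.kernel, self.stride)
        windows = sliding_window_view(x, self.kernel, axis=2)[:, :, ::self.stride]
        # (N, C_in, L_out, K) -> (N, L_out, C_in*K)
        cols = windows.transpose(0, 2, 1, 3).reshape(x.shape[0], l_out, -1)
        self._cols = cols
        w2 = self.W.reshape(self.out_channels, -1)
        out = cols @ w2.T  # (N, L_out, C_out)
        if self.b is not None:
            out += self.b
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, grad_out):
        # grad_out: (N, C_out, L_out)
        n, _, l_out = grad_out.shape
        g = grad_out.transpose(0, 2, 1).reshape(n * l_out, self.out_channels)
        cols = self._cols.reshape(n * l_out, -1)
        self.dW = (g.T @ cols).reshape(self.W.shape)
        if self.b is not None:
            self.db = grad_out.sum(axis=(0, 2))
        dcols = (g @ self.W.reshape(self.out_channels, -1)).reshape(
            n, l_out, self.in_channels, self.kernel)
        dx = np.zeros_like(self._x)
        for k in range(self.kernel):
            dx[:, :, k:k + l_out * self.stride:self.stride] += \
                dcols[:, :, :, k].transpose(0, 2, 1)
        return dx

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def gradients(self):
        return [self.dW] + ([self.db] if self.b is not None else [])


class Linear(Layer):
    trainable = True

    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        self.W = np.zeros((out_features, in_features))
        self.b = np.zeros(out_features) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._x: Optional[np.ndarray] = None

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.in_features:
            raise NetworkError(
                f"linear expected {self.in_features} features, got {x.shape[1]}"
            )
        self._x = x
        out = x @ self.W.T
        if self.b is not None:
            out += self.b
        return out

    def backward(self, grad_out):
        self.dW = grad_out.T @ self._x
        if self.b is not None:
            self.db = grad_out.sum(axis=0)
        return grad_out @ self.W

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def gradients(self):
        return [self.dW] + ([self.db] if self.b is not None else [])


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out):
        return grad_out * self._mask


class MaxPool1d(Layer):
    def __init__(self, window: int):
        self.window = window

    def forward(self, x, training=False, rng=None):
        n, c, length = x.shape
        l_out = pool_output_length(length, self.window)
        self._in_length = length
        trimmed = x[:, :, :l_out * self.window].reshape(n, c, l_out, self.window)
        self._windows = trimmed
        self._argmax = trimmed.argmax(axis=3)
        return trimmed.max(axis=3)

    def backward(self, grad_out):
        # training gradient routes to the first maximum, like the recorded argmax
        n, c, l_out = grad_out.shape
        dwin = np.zeros_like(self._windows)
        np.put_along_axis(dwin, self._argmax[..., None], grad_out[..., None], axis=3)
        dx = np.zeros((n, c, self._in_length))
        dx[:, :, :l_out * self.window] = dwin.reshape(n, c, l_out * self.window)
        return dx


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference and during explanation."""

    def __init__(self, p: float):
        if not (0.0 <= p < 1.0):
            raise NetworkError(f"dropout rate must lie in [0, 1), got {p}")
        self.p = p
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise NetworkError("training-mode dropout requires an explicit RNG")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class Network:
    """An ordered stack of layers mapping (N, input_length) to (N, n_classes)."""

    def __init__(self, layers: list[Layer], spec: Optional[NetworkSpec] = None):
        self.layers = layers
        self.spec = spec
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    @property
    def input_length(self) -> int:
        if self.spec is not None:
            return self.spec.input_length
        first = next(l for l in self.layers if isinstance(l, (Conv1d, Linear)))
        return first.in_features if isinstance(first, Linear) else None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if isinstance(self.layers[0], Conv1d):
            return X[:, None, :]  # single input channel
        return X

    def forward(self, X: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        h = self._prepare(X)
        for layer in self.layers:
            h = layer.forward(h, training=training, rng=rng)
        return h

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        g = grad_logits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        if g.ndim == 3:  # undo the channel axis added by _prepare
            g = g.reshape(g.shape[0], -1)
        return g

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.gradients()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: spec JSON + per-layer weight arrays."""
        import json
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.parameters()):
                arrays[f"layer{i}_p{j}"] = p
        spec_blob = json.dumps(self.spec.__dict__, default=list) if self.spec else ""
        np.savez(path, __spec__=np.array(spec_blob), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        import json
        blob = np.load(path, allow_pickle=False)
        spec_json = str(blob["__spec__"])
        spec_dict = json.loads(spec_json)
        spec = NetworkSpec(
            input_length=spec_dict["input_length"],
            blocks=tuple(spec_dict["blocks"]),
            kernel=spec_dict["kernel"], stride=spec_dict["stride"],
            padding=spec_dict["padding"], pool_window=spec_dict["pool_window"],
            fc_sizes=tuple(spec_dict["fc_sizes"]), dropout=spec_dict["dropout"],
        )
        net = build_network(spec, seed=0)
        for i, layer in enumerate(net.layers):
            for j, p in enumerate(layer.parameters()):
                p[...] = blob[f"layer{i}_p{j}"]
        return net


def kaiming_uniform(shape: tuple[int, ...], fan_in: int,
                    rng: np.random.Generator) -> np.ndarray:
    """He-uniform initialization for ReLU layers: U(±sqrt(6 / fan_in))."""
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


def build_network(spec: NetworkSpec, seed: int) -> Network:
    """Instantiate the block architecture with Kaiming-uniform weights.

    Raises :class:`NetworkError` if the architecture shrinks the signal below the
    kernel/pool size before the blocks are exhausted.
    """
    spec.block_lengths()  # validates shape recursion before any allocation
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    in_channels = 1
    for out_channels in spec.blocks:
        conv = Conv1d(in_channels, out_channels, spec.kernel, spec.stride)
        fan_in = in_channels * spec.kernel
        conv.W = kaiming_uniform(conv.W.shape, fan_in, rng)
        layers += [conv, ReLU(), MaxPool1d(spec.pool_window)]
        in_channels = out_channels
    layers.append(Flatten())
    n_in = spec.flatten_length
    for i, n_out in enumerate(spec.fc_sizes):
        linear = Linear(n_in, n_out)
        linear.W = kaiming_uniform(linear.W.shape, n_in, rng)
        layers.append(linear)
        if i < len(spec.fc_sizes) - 1:
            layers.append(ReLU())
            if spec.dropout > 0:
                layers.append(Dropout(spec.dropout))
        n_in = n_out
    return Network(layers, spec=spec)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (defaults: the receptor-scale settings)."""

    epochs: int = 500
    batch_size: int = 1024
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0 \
                or self.weight_decay < 0:
            raise NetworkError(f"invalid training configuration: {self}")


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = float(-np.log(p[np.arange(n), y] + 1e-300).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def train(model: Network, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig) -> Network:
    """Mini-batch Adam with cross-entropy loss and L2 weight decay.

    Shuffling is reseeded per epoch from the master seed; dropout is active
    during training only.  Per-epoch mean loss and training accuracy are
    recorded in ``model.history``.  Zero epochs returns the model unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    params = model.parameters()
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    master = np.random.default_rng(cfg.seed)
    dropout_rng = np.random.default_rng(master.integers(2**31))
    for epoch in range(cfg.epochs):
        order = np.random.default_rng(cfg.seed + 1 + epoch).permutation(len(X))
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, len(X), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            logits = model.forward(X[batch], training=True, rng=dropout_rng)
            loss, grad = softmax_cross_entropy(logits, y[batch])
            if not np.isfinite(loss):
                raise NetworkError(
                    f"non-finite loss at epoch {epoch}: learning likely diverged"
                )
            model.backward(grad)
            step += 1
            grads = model.gradients()
            for p, g, m_, v_ in zip(params, grads, m_state, v_state):
                if cfg.weight_decay:
                    g = g + cfg.weight_decay * p
                m_[...] = beta1 * m_ + (1 - beta1) * g
                v_[...] = beta2 * v_ + (1 - beta2) * g * g
                m_hat = m_ / (1 - beta1 ** step)
                v_hat = v_ / (1 - beta2 ** step)
                p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            epoch_loss += loss * len(batch)
            epoch_correct += int((logits.argmax(axis=1) == y[batch]).sum())
        model.history["loss"].append(epoch_loss / len(X))
        model.history["accuracy"].append(epoch_correct / len(X))
    return model


def predict(model: Network, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (logits, predicted class indices); argmax ties go to the
    lowest class index."""
    logits = model.forward(X, training=False)
    return logits, logits.argmax(axis=1)


def input_gradient(model: Network, x: np.ndarray, class_idx: int) -> np.ndarray:
    """Gradient of one class logit with respect to the input vector.

    Uses the same backward machinery as training (dropout inactive); serves
    as the independent oracle for the gradient×input identity of the basic
    relevance rule on bias-free ReLU networks.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    logits = model.forward(x, training=False)
    seed = np.zeros_like(logits)
    seed[:, class_idx] = 1.0
    return model.backward(seed)[0]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-class precision/recall/F1 with macro-F1, accuracy, and the
    row-normalized confusion matrix (rows: true class, fixed state order)."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_f1: float
    accuracy: float
    confusion: np.ndarray            # raw counts
    confusion_normalized: np.ndarray  # rows sum to 1 for nonempty classes

    def to_frame(self):
        import pandas as pd
        rows = [
            {"class": STATES[c], "precision": self.precision[c],
             "recall": self.recall[c], "f1": self.f1[c],
             "support": int(self.support[c])}
            for c in range(len(STATES))
        ]
        rows.append({"class": "macro avg", "precision": np.nan, "recall": np.nan,
                     "f1": self.macro_f1, "support": int(self.support.sum())})
        rows.append({"class": "accuracy", "precision": np.nan, "recall": np.nan,
                     "f1": self.accuracy, "support": int(self.support.sum())})
        return pd.DataFrame(rows)


def evaluate(model: Network, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Classification report over the fixed three-state class order."""
    y = np.asarray(y, dtype=np.int64)
    if len(y) == 0:
        raise NetworkError("cannot evaluate on an empty set")
    _, y_hat = predict(model, X)
    return report_from_predictions(y, y_hat)


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    labels = list(range(len(STATES)))
    precision, recall, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0.0)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, row_sums, out=np.zeros(cm.shape, dtype=float),
                        where=row_sums > 0)
    return EvalReport(
        precision=precision, recall=recall, f1=f1,
        support=support.astype(int),
        macro_f1=float(f1.mean()),
        accuracy=float(np.trace(cm) / cm.sum()),
        confusion=cm, confusion_normalized=cm_norm,
    )
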