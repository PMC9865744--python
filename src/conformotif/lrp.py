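"""Layer-wise relevance propagation (basic and ε-stabilized rules).

A prediction is explained by seeding the output layer with the explained
class's raw logit and redistributing that relevance backwards, layer by
layer, onto the input features.  For two neurons j (lower) and k (upper),
the basic rule assigns

    R_j = Σ_k  a_j w_jk / z_k · R_k,      z_k = Σ_{0,j} a_j w_jk,

where the denominator sum runs over all lower neurons and the bias term
(index 0).  The ε rule adds a small positive stabilizer to the denominator,
here applied sign-matched (ε·sign(z_k), with sign(0) = +1) so near-zero
denominators are damped without flipping signs.  The bias participates in
the denominator but its share of relevance is absorbed, so conservation of
the per-layer relevance sum is exact only for bias-free networks under ε=0.

Pooling redistributes winner-takes-all onto the recorded forward maxima
(ties split equally); ReLU and dropout pass relevance through unchanged.
All rules operate directly on stored weights and recorded activations, and
each is unit-testable against brute-force oracles (unrolled convolution
matrices; gradient×input for bias-free ReLU networks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import (Conv1d, Dropout, Flatten, Linear, MaxPool1d, Network,
                      ReLU, conv_output_length)


class LRPError(ValueError):
    pass


@dataclass(frozen=True)
class LRPConfig:
    """Propagation rule selection.

    ``rule`` is ``"lrp0"`` (basic) or ``"lrp_epsilon"``; ``epsilon`` is the
    nonnegative stabilizer (with ε=0 the two rules coincide).
    """

    rule: str = "lrp_epsilon"
    epsilon: float = 1e-2

    def __post_init__(self) -> None:
        if self.rule not in ("lrp0", "lrp_epsilon"):
            raise LRPError(f"unknown rule {self.rule!r}")
        if self.epsilon < 0:
            raise LRPError("epsilon must be nonnegative")
        if self.rule == "lrp0":
            object.__setattr__(self, "epsilon", 0.0)


@dataclass
class ActivationTrace:
    """Input activation of every layer during one forward pass, plus logits."""

    inputs: list[np.ndarray]
    logits: np.ndarray


def record_activations(model: Network, x: np.ndarray) -> ActivationTrace:
    """Run one inference forward pass, recording each layer's input.

    ``x`` is a single flattened feature vector; the trace's logits equal the
    model's prediction logits exactly (dropout disabled).
    """
    h = model._prepare(np.atleast_2d(np.asarray(x, dtype=float)))
    inputs: list[np.ndarray] = []
    for layer in model.layers:
        inputs.append(h[0].copy())
        h = layer.forward(h, training=False)
    return ActivationTrace(inputs=inputs, logits=h[0].copy())


def seed_output_relevance(logits: np.ndarray, class_idx: int) -> np.ndarray:
    """Initial output-layer relevance: the explained class keeps its raw
    logit, every other entry is zero."""
    logits = np.asarray(logits, dtype=float)
    if not (0 <= class_idx < logits.shape[-1]):
        raise LRPError(f"class index {class_idx} out of range for {logits.shape[-1]} classes")
    seed = np.zeros_like(logits)
    seed[class_idx] = logits[class_idx]
    return seed


def _stabilized_shares(z: np.ndarray, r_upper: np.ndarray, epsilon: float) -> np.ndarray:
    """R_k / (z_k + ε·sign(z_k)), with 0/0 treated as a zero share."""
    zs = z + epsilon * np.where(z >= 0, 1.0, -1.0)
    zero = zs == 0
    if np.any(zero & (np.asarray(r_upper) != 0)):
        raise LRPError(
            "exact zero denominator under the basic rule; use the ε rule "
            "(rule='lrp_epsilon') to stabilize"
        )
    return np.divide(r_upper, zs, out=np.zeros_like(zs, dtype=float), where=~zero)


def lrp_dense(a: np.ndarray, W: np.ndarray, b: Optional[np.ndarray],
              r_upper: np.ndarray, cfg: LRPConfig) -> np.ndarray:
    """Propagate relevance through a dense layer.

    ``W`` has shape (J, K) with ``W[j, k]`` the weight from lower neuron j to
    upper neuron k (the w_jk of the rule); ``z_k = Σ_j a_j w_jk + b_k``.
    """
    a = np.asarray(a, dtype=float)
    W = np.asarray(W, dtype=float)
    z = a @ W
    if b is not None:
        z = z + b
    s = _stabilized_shares(z, np.asarray(r_upper, dtype=float), cfg.epsilon)
    return a * (W @ s)


def lrp_conv1d(a: np.ndarray, W: np.ndarray, b: Optional[np.ndarray],
               r_upper: np.ndarray, cfg: LRPConfig, stride: int = 1) -> np.ndarray:
    """Propagate relevance through a 1-D convolution under weight sharing.

    ``a``: (C_in, L) layer input; ``W``: (C_out, C_in, K) kernels;
    ``r_upper``: (C_out, L_out).  Numerically identical to :func:`lrp_dense`
    on the unrolled convolution matrix.
    """
    a = np.asarray(a, dtype=float)
    W = np.asarray(W, dtype=float)
    c_out, c_in, kernel = W.shape
    if a.shape[0] != c_in:
        raise LRPError(f"conv LRP expected {c_in} channels, got {a.shape[0]}")
    l_out = conv_output_length(a.shape[1], kernel, stride)
    from numpy.lib.stride_tricks import sliding_window_view
    windows = sliding_window_view(a, kernel, axis=1)[:, ::stride]  # (C_in, L_out, K)
    z = np.einsum("oik,ilk->ol", W, windows)
    if b is not None:
        z = z + b[:, None]
    s = _stabilized_shares(z, np.asarray(r_upper, dtype=float), cfg.epsilon)
    # scatter s·w back onto the input positions each window covers
    contrib = np.einsum("oik,ol->ilk", W, s)  # (C_in, L_out, K)
    r_lower = np.zeros_like(a)
    for k in range(kernel):
        r_lower[:, k:k + l_out * stride:stride] += contrib[:, :, k]
    return a * r_lower


def lrp_maxpool(a: np.ndarray, r_upper: np.ndarray, window: int) -> np.ndarray:
    """Winner-takes-all redistribution onto each pooling window's maxima.

    Ties split the window's relevance equally; positions beyond the last
    full window (odd lengths) receive zero.  Conserves the relevance sum.
    """
    a = np.asarray(a, dtype=float)
    c, length = a.shape
    l_out = length // window
    if r_upper.shape != (c, l_out):
        raise LRPError(f"pool relevance shape {r_upper.shape} != {(c, l_out)}")
    trimmed = a[:, :l_out * window].reshape(c, l_out, window)
    is_max = trimmed == trimmed.max(axis=2, keepdims=True)
    shares = is_max / is_max.sum(axis=2, keepdims=True)
    r = shares * np.asarray(r_upper, dtype=float)[:, :, None]
    r_lower = np.zeros_like(a)
    r_lower[:, :l_out * window] = r.reshape(c, l_out * window)
    return r_lower


def lrp_relu(r_upper: np.ndarray) -> np.ndarray:
    """Identity pass-through: the rule's activations are already the ReLU
    outputs, so the nonlinearity re-routes nothing."""
    return np.asarray(r_upper, dtype=float)


@dataclass
class Explanation:
    """Input-layer relevance plus the per-layer relevance stack."""

    class_idx: int
    input_relevance: np.ndarray          # length 3M
    layer_relevances: list[np.ndarray]    # one per layer, bottom-up order
    layer_names: list[str]
    seed: float
    logits: np.ndarray


def explain(model: Network, x: np.ndarray, class_idx: int,
            cfg: LRPConfig | None = None,
            trace: ActivationTrace | None = None) -> Explanation:
    """Full backward relevance pass from the seeded logit to the input."""
    cfg = cfg or LRPConfig()
    if trace is None:
        trace = record_activations(model, x)
    r = seed_output_relevance(trace.logits, class_idx)
    seed_value = float(r.sum())
    relevances: list[np.ndarray] = [r]
    names: list[str] = ["output"]
    for layer, a in zip(reversed(model.layers), reversed(trace.inputs)):
        if isinstance(layer, Linear):
            r = lrp_dense(a, layer.W.T, layer.b, r, cfg)
        elif isinstance(layer, Conv1d):
            r = lrp_conv1d(a, layer.W, layer.b, r, cfg, stride=layer.stride)
        elif isinstance(layer, MaxPool1d):
            r = lrp_maxpool(a, r, layer.window)
        elif isinstance(layer, Flatten):
            r = r.reshape(a.shape)
        elif isinstance(layer, (ReLU, Dropout)):
            r = lrp_relu(r)
        else:  # pragma: no cover
            raise LRPError(f"no relevance rule for layer {type(layer).__name__}")
        relevances.append(r)
        names.append(type(layer).__name__)
    relevances.reverse()
    names.reverse()
    return Explanation(
        class_idx=class_idx,
        input_relevance=relevances[0].reshape(-1),
        layer_relevances=relevances,
        layer_names=names,
        seed=seed_value,
        logits=trace.logits,
    )


def conservation_report(explanation: Explanation):
    """Per-layer relevance sums and their deficits relative to the seed.

    For a bias-free network under ε=0 every deficit is numerically zero;
    with biases or ε>0 the report quantifies the relevance absorbed at each
    stage.  Returns a pandas DataFrame (layer, relevance_sum, deficit).
    """
    import pandas as pd
    rows = []
    for name, r in zip(explanation.layer_names, explanation.layer_relevances):
        total = float(np.sum(r))
        rows.append({"layer": name, "relevance_sum": total,
                     "deficit": explanation.seed - total})
    return pd.DataFrame(rows)
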