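"""Reference implementations of the network's building-block math.

These are plain-array forward computations: the LSTM gate recurrences,
the bidirectional wrapper, the multi-scale 1-D convolution block, and
scaled dot-product attention.  The trainable layers in
:mod:`eegfuse.nn.layers` implement the same math with cached
intermediates and backward passes; tests assert the two routes agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "relu",
    "leaky_relu",
    "sigmoid",
    "softmax",
    "standardize",
    "LSTMCellParams",
    "LSTMState",
    "lstm_cell_step",
    "bilstm_layer",
    "multiscale_conv_block",
    "conv1d_same",
    "AttentionTensors",
    "dot_product_attention",
]


def relu(x: np.ndarray) -> np.ndarray:
    """Element-wise ``max(0, x)``."""
    return np.maximum(0, np.asarray(x))


def leaky_relu(x: np.ndarray, a: float = 0.01) -> np.ndarray:
    """Element-wise ``a*x`` for negative entries, identity otherwise."""
    x = np.asarray(x)
    return np.where(x < 0, a * x, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-branch form
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Row-stochastic exponential normalization along ``axis``."""
    x = np.asarray(x, dtype=float)
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def standardize(x: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-sample, per-feature standardization along the sequence axis.

    ``x`` is (..., sequence, features); each feature channel of each
    sample is centered and divided by its population SD plus ``eps``
    (constant channels therefore map to zeros).
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=-2, keepdims=True)
    sd = x.std(axis=-2, keepdims=True)
    return (x - mean) / (sd + eps)


# ---------------------------------------------------------------------------
# LSTM

@dataclass
class LSTMCellParams:
    """Weights of one LSTM cell, one (input, hidden, bias, bias) quadruple
    per gate: forget ``f``, input ``i``, candidate ``g``, output ``o``.

    Input weights are (hidden, input); hidden weights (hidden, hidden);
    biases (hidden,).
    """

    w_if: np.ndarray
    w_hf: np.ndarray
    b_if: np.ndarray
    b_hf: np.ndarray
    w_ii: np.ndarray
    w_hi: np.ndarray
    b_ii: np.ndarray
    b_hi: np.ndarray
    w_ig: np.ndarray
    w_hg: np.ndarray
    b_ig: np.ndarray
    b_hg: np.ndarray
    w_io: np.ndarray
    w_ho: np.ndarray
    b_io: np.ndarray
    b_ho: np.ndarray

    def __post_init__(self) -> None:
        h, i = np.shape(self.w_if)
        for name in ("w_if", "w_ii", "w_ig", "w_io"):
            if np.shape(getattr(self, name)) != (h, i):
                raise ValueError(f"{name} must have shape {(h, i)}")
        for name in ("w_hf", "w_hi", "w_hg", "w_ho"):
            if np.shape(getattr(self, name)) != (h, h):
                raise ValueError(f"{name} must have shape {(h, h)}")
        for name in ("b_if", "b_hf", "b_ii", "b_hi", "b_ig", "b_hg", "b_io", "b_ho"):
            if np.shape(getattr(self, name)) != (h,):
                raise ValueError(f"{name} must have shape {(h,)}")
        for name, arr in vars(self).items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def hidden_size(self) -> int:
        return self.w_if.shape[0]

    @property
    def input_size(self) -> int:
        return self.w_if.shape[1]

    @classmethod
    def zeros(cls, hidden: int, inputs: int) -> "LSTMCellParams":
        h, i = hidden, inputs
        z = np.zeros
        return cls(
            z((h, i)), z((h, h)), z(h), z(h),
            z((h, i)), z((h, h)), z(h), z(h),
            z((h, i)), z((h, h)), z(h), z(h),
            z((h, i)), z((h, h)), z(h), z(h),
        )

    @classmethod
    def random(cls, hidden: int, inputs: int, rng: np.random.Generator,
               scale: float = 0.5) -> "LSTMCellParams":
        def w(*shape):
            return rng.uniform(-scale, scale, size=shape)

        return cls(
            w(hidden, inputs), w(hidden, hidden), w(hidden), w(hidden),
            w(hidden, inputs), w(hidden, hidden), w(hidden), w(hidden),
            w(hidden, inputs), w(hidden, hidden), w(hidden), w(hidden),
            w(hidden, inputs), w(hidden, hidden), w(hidden), w(hidden),
        )


@dataclass
class LSTMState:
    """Hidden and cell vectors ``(h_t, c_t)`` of one LSTM cell."""

    h: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.h.shape != self.c.shape:
            raise ValueError(f"h and c must share a shape: {self.h.shape} vs {self.c.shape}")

    @classmethod
    def zeros(cls, hidden: int) -> "LSTMState":
        return cls(np.zeros(hidden), np.zeros(hidden))


def lstm_cell_step(x_t: np.ndarray, prev: LSTMState, params: LSTMCellParams) -> LSTMState:
    """One LSTM time step.

    Gates: ``f_t, i_t = sigmoid`` and ``g_t = tanh`` of their affine forms
    in ``x_t`` and ``h_{t-1}``; then ``c_t = f_t*c_{t-1} + i_t*g_t``,
    ``o_t = sigmoid(...)`` and ``h_t = o_t * tanh(c_t)``.
    """
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (params.input_size,):
        raise ValueError(
            f"x_t has shape {x_t.shape}, expected ({params.input_size},) for these params"
        )
    if prev.h.shape != (params.hidden_size,):
        raise ValueError(
            f"prev.h has shape {prev.h.shape}, expected ({params.hidden_size},)"
        )
    p = params
    f = sigmoid(p.w_if @ x_t + p.b_if + p.w_hf @ prev.h + p.b_hf)
    i = sigmoid(p.w_ii @ x_t + p.b_ii + p.w_hi @ prev.h + p.b_hi)
    g = np.tanh(p.w_ig @ x_t + p.b_ig + p.w_hg @ prev.h + p.b_hg)
    c = f * prev.c + i * g
    o = sigmoid(p.w_io @ x_t + p.b_io + p.w_ho @ prev.h + p.b_ho)
    h = o * np.tanh(c)
    return LSTMState(h, c)


def bilstm_layer(
    sequence: np.ndarray, fwd: LSTMCellParams, bwd: LSTMCellParams
) -> np.ndarray:
    """Bidirectional LSTM over an (S, F) sequence from zero initial states.

    Returns (S, 2H): per-step forward outputs in the first H columns,
    backward outputs (computed over the reversed sequence and re-reversed)
    in the last H.
    """
    sequence = np.asarray(sequence, dtype=float)
    if sequence.ndim != 2 or sequence.shape[0] < 1:
        raise ValueError(f"sequence must be a non-empty (S, F) array, got {sequence.shape}")
    s_len = sequence.shape[0]
    out = np.empty((s_len, fwd.hidden_size + bwd.hidden_size))
    state = LSTMState.zeros(fwd.hidden_size)
    for t in range(s_len):
        state = lstm_cell_step(sequence[t], state, fwd)
        out[t, : fwd.hidden_size] = state.h
    state = LSTMState.zeros(bwd.hidden_size)
    for t in range(s_len - 1, -1, -1):
        state = lstm_cell_step(sequence[t], state, bwd)
        out[t, fwd.hidden_size :] = state.h
    return out


# ---------------------------------------------------------------------------
# Convolution

def conv1d_same(sequence: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Length-preserving 1-D convolution along the sequence axis.

    ``sequence`` (S, F), ``weights`` (k, F, O), ``bias`` (O,); zero
    padding of floor((k-1)/2) left and ceil((k-1)/2) right.
    """
    sequence = np.asarray(sequence, dtype=float)
    k = weights.shape[0]
    s_len = sequence.shape[0]
    if s_len < k:
        raise ValueError(f"sequence length {s_len} shorter than kernel width {k}")
    left = (k - 1) // 2
    right = k - 1 - left
    padded = np.pad(sequence, ((left, right), (0, 0)))
    out = np.broadcast_to(bias, (s_len, weights.shape[2])).copy()
    for j in range(k):
        out += padded[j : j + s_len] @ weights[j]
    return out


def multiscale_conv_block(
    sequence: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    activation: str = "relu",
    leaky_slope: float = 0.01,
) -> np.ndarray:
    """Parallel 1-D convolution branches concatenated on the feature axis.

    One branch per entry of ``weights`` (each (k_i, F, n_filters)); every
    branch uses 'same' padding so outputs share the sequence length and
    concatenate to (S, sum of branch filters).
    """
    if len(weights) != len(biases) or not weights:
        raise ValueError("weights and biases must be non-empty lists of equal length")
    act = {"relu": relu, "leaky_relu": lambda v: leaky_relu(v, leaky_slope)}[activation]
    return np.concatenate(
        [act(conv1d_same(sequence, w, b)) for w, b in zip(weights, biases)], axis=-1
    )


# ---------------------------------------------------------------------------
# Attention

@dataclass
class AttentionTensors:
    """Query/key/value matrices with the key dimensionality ``d_k``."""

    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    d_k: int

    def __post_init__(self) -> None:
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        if self.d_k < 1:
            raise ValueError(f"d_k must be >= 1, got {self.d_k}")
        if self.Q.shape[1] != self.d_k or self.K.shape[1] != self.d_k:
            raise ValueError(
                f"Q and K must have d_k={self.d_k} columns, got "
                f"{self.Q.shape[1]} and {self.K.shape[1]}"
            )
        if self.K.shape[0] != self.V.shape[0]:
            raise ValueError(
                f"K and V must share their row count, got {self.K.shape[0]} "
                f"and {self.V.shape[0]}"
            )


def dot_product_attention(
    t: AttentionTensors, return_weights: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention ``softmax(Q K^T / sqrt(d_k)) V``.

    Scores are query-key similarities scaled by ``1/sqrt(d_k)``; the
    row-wise softmax turns each query's scores into a probability
    distribution over keys, which weights the value rows.
    """
    scores = (t.Q @ t.K.T) / np.sqrt(t.d_k)
    weights = softmax(scores, axis=-1)
    output = weights @ t.V
    return (output, weights) if return_weights else output
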