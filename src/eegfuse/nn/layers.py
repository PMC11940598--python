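"""Trainable layers: forward passes with cached intermediates and
analytic backward passes, on plain NumPy arrays.

Every layer exposes ``parameters()`` (list of :class:`Parameter`),
``forward(x)`` and ``backward(dy)``; ``backward`` returns the gradient
with respect to the layer input and accumulates parameter gradients in
place.  Batched inputs are (batch, sequence, features) unless noted.
Correctness of each backward pass is pinned by central-difference
gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

from .functional import softmax

__all__ = [
    "Parameter",
    "Dense",
    "MultiScaleConv1D",
    "BiLSTM",
    "SelfAttention",
    "MeanPoolSeq",
    "glorot_uniform",
    "softmax_cross_entropy",
]


class Parameter:
    """A weight array together with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def size(self) -> int:
        return self.value.size


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _act_forward(pre: np.ndarray, activation: str | None, slope: float) -> np.ndarray:
    if activation is None:
        return pre
    if activation == "relu":
        return np.maximum(0, pre)
    if activation == "leaky_relu":
        return np.where(pre < 0, slope * pre, pre)
    raise ValueError(f"unknown activation {activation!r}")


def _act_backward(dy: np.ndarray, pre: np.ndarray, activation: str | None,
                  slope: float) -> np.ndarray:
    if activation is None:
        return dy
    if activation == "relu":
        return dy * (pre > 0)
    if activation == "leaky_relu":
        return dy * np.where(pre < 0, slope, 1.0)
    raise ValueError(f"unknown activation {activation!r}")


class Dense:
    """Affine map along the last axis with optional activation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None, leaky_slope: float = 0.01,
                 dtype=np.float32, name: str = "dense") -> None:
        self.w = Parameter(glorot_uniform(rng, n_in, n_out, (n_in, n_out), dtype),
                           f"{name}.w")
        self.b = Parameter(np.zeros(n_out, dtype=dtype), f"{name}.b")
        self.activation = activation
        self.leaky_slope = leaky_slope
        self._x: np.ndarray | None = None
        self._pre: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._pre = x @ self.w.value + self.b.value
        return _act_forward(self._pre, self.activation, self.leaky_slope)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dpre = _act_backward(dy, self._pre, self.activation, self.leaky_slope)
        x2 = self._x.reshape(-1, self.w.value.shape[0])
        d2 = dpre.reshape(-1, self.w.value.shape[1])
        self.w.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return dpre @ self.w.value.T


class MultiScaleConv1D:
    """Parallel length-preserving 1-D conv branches, one per kernel size,
    concatenated on the feature axis after the activation."""

    def __init__(self, n_in: int, n_filters: int, kernel_sizes: list[int],
                 rng: np.random.Generator, activation: str = "relu",
                 leaky_slope: float = 0.01, dtype=np.float32) -> None:
        if not kernel_sizes or any(k < 1 for k in kernel_sizes):
            raise ValueError(f"kernel_sizes must be non-empty, all >= 1: {kernel_sizes}")
        self.kernel_sizes = list(kernel_sizes)
        self.n_filters = n_filters
        self.weights = [
            Parameter(
                glorot_uniform(rng, k * n_in, n_filters, (k, n_in, n_filters), dtype),
                f"conv{k}.w",
            )
            for k in kernel_sizes
        ]
        self.biases = [
            Parameter(np.zeros(n_filters, dtype=dtype), f"conv{k}.b")
            for k in kernel_sizes
        ]
        self.activation = activation
        self.leaky_slope = leaky_slope
        self._cache: list[tuple[np.ndarray, np.ndarray]] = []

    @property
    def n_out(self) -> int:
        return self.n_filters * len(self.kernel_sizes)

    def parameters(self) -> list[Parameter]:
        return [p for pair in zip(self.weights, self.biases) for p in pair]

    def forward(self, x: np.ndarray) -> np.ndarray:
        s_len = x.shape[1]
        if s_len < max(self.kernel_sizes):
            raise ValueError(
                f"sequence length {s_len} shorter than largest kernel "
                f"{max(self.kernel_sizes)}"
            )
        self._cache = []
        outs = []
        for k, w, b in zip(self.kernel_sizes, self.weights, self.biases):
            left = (k - 1) // 2
            padded = np.pad(x, ((0, 0), (left, k - 1 - left), (0, 0)))
            pre = np.broadcast_to(b.value, (x.shape[0], s_len, self.n_filters)).copy()
            for j in range(k):
                pre += padded[:, j : j + s_len] @ w.value[j]
            self._cache.append((padded, pre))
            outs.append(_act_forward(pre, self.activation, self.leaky_slope))
        return np.concatenate(outs, axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = None
        for idx, (k, w, b) in enumerate(zip(self.kernel_sizes, self.weights, self.biases)):
            padded, pre = self._cache[idx]
            s_len = pre.shape[1]
            left = (k - 1) // 2
            dbranch = dy[..., idx * self.n_filters : (idx + 1) * self.n_filters]
            dpre = _act_backward(dbranch, pre, self.activation, self.leaky_slope)
            b.grad += dpre.sum(axis=(0, 1))
            dpadded = np.zeros_like(padded)
            d2 = dpre.reshape(-1, self.n_filters)
            for j in range(k):
                seg = padded[:, j : j + s_len].reshape(-1, padded.shape[2])
                w.grad[j] += seg.T @ d2
                dpadded[:, j : j + s_len] += dpre @ w.value[j].T
            contrib = dpadded[:, left : left + s_len]
            dx = contrib if dx is None else dx + contrib
        return dx


class _LSTMDirection:
    """One direction of an LSTM over (batch, sequence, input).

    Gate order in the stacked matrices is i, f, g, o.  The math per step
    matches :func:`eegfuse.nn.functional.lstm_cell_step`; the backward
    pass is standard truncated-nowhere backpropagation through time.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "lstm") -> None:
        self.hidden = hidden
        self.w_x = Parameter(
            glorot_uniform(rng, n_in, hidden, (n_in, 4 * hidden), dtype), f"{name}.w_x"
        )
        self.w_h = Parameter(
            glorot_uniform(rng, hidden, hidden, (hidden, 4 * hidden), dtype),
            f"{name}.w_h",
        )
        self.b = Parameter(np.zeros(4 * hidden, dtype=dtype), f"{name}.b")
        self._cache: dict[str, np.ndarray] | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w_x, self.w_h, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        bsz, s_len, _ = x.shape
        hid = self.hidden
        xp = x @ self.w_x.value + self.b.value  # (B, S, 4H)
        gi = np.empty((bsz, s_len, hid), dtype=xp.dtype)
        gf = np.empty_like(gi)
        gg = np.empty_like(gi)
        go = np.empty_like(gi)
        cs = np.empty_like(gi)
        tc = np.empty_like(gi)
        hs = np.empty_like(gi)
        h = np.zeros((bsz, hid), dtype=xp.dtype)
        c = np.zeros((bsz, hid), dtype=xp.dtype)
        for t in range(s_len):
            a = xp[:, t] + h @ self.w_h.value
            i = 1.0 / (1.0 + np.exp(-a[:, :hid]))
            f = 1.0 / (1.0 + np.exp(-a[:, hid : 2 * hid]))
            g = np.tanh(a[:, 2 * hid : 3 * hid])
            o = 1.0 / (1.0 + np.exp(-a[:, 3 * hid :]))
            c = f * c + i * g
            th = np.tanh(c)
            h = o * th
            gi[:, t], gf[:, t], gg[:, t], go[:, t] = i, f, g, o
            cs[:, t], tc[:, t], hs[:, t] = c, th, h
        self._cache = dict(x=x, gi=gi, gf=gf, gg=gg, go=go, cs=cs, tc=tc, hs=hs)
        return hs

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        cc = self._cache
        x, gi, gf, gg, go = cc["x"], cc["gi"], cc["gf"], cc["gg"], cc["go"]
        cs, tc, hs = cc["cs"], cc["tc"], cc["hs"]
        bsz, s_len, hid = gi.shape
        da_all = np.empty((bsz, s_len, 4 * hid), dtype=gi.dtype)
        dh_next = np.zeros((bsz, hid), dtype=gi.dtype)
        dc_next = np.zeros((bsz, hid), dtype=gi.dtype)
        for t in range(s_len - 1, -1, -1):
            dh = dh_out[:, t] + dh_next
            i, f, g, o = gi[:, t], gf[:, t], gg[:, t], go[:, t]
            th = tc[:, t]
            do = dh * th
            dc = dc_next + dh * o * (1.0 - th * th)
            c_prev = cs[:, t - 1] if t > 0 else np.zeros_like(dc)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros_like(dh)
            da = da_all[:, t]
            da[:, :hid] = dc * g * i * (1.0 - i)
            da[:, hid : 2 * hid] = dc * c_prev * f * (1.0 - f)
            da[:, 2 * hid : 3 * hid] = dc * i * (1.0 - g * g)
            da[:, 3 * hid :] = do * o * (1.0 - o)
            self.w_h.grad += h_prev.T @ da
            dh_next = da @ self.w_h.value.T
            dc_next = dc * f
        d2 = da_all.reshape(-1, 4 * hid)
        self.w_x.grad += x.reshape(-1, x.shape[2]).T @ d2
        self.b.grad += d2.sum(axis=0)
        return da_all @ self.w_x.value.T


class BiLSTM:
    """Bidirectional LSTM: forward and reversed passes concatenated
    per step to (batch, sequence, 2*hidden)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.fwd = _LSTMDirection(n_in, hidden, rng, dtype, "bilstm.fwd")
        self.bwd = _LSTMDirection(n_in, hidden, rng, dtype, "bilstm.bwd")
        self.hidden = hidden

    @property
    def n_out(self) -> int:
        return 2 * self.hidden

    def parameters(self) -> list[Parameter]:
        return self.fwd.parameters() + self.bwd.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] < 1:
            raise ValueError("empty sequence")
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        hid = self.hidden
        dxf = self.fwd.backward(np.ascontiguousarray(dy[..., :hid]))
        dxb = self.bwd.backward(np.ascontiguousarray(dy[:, ::-1, hid:]))[:, ::-1]
        return dxf + dxb


class SelfAttention:
    """Single-head scaled dot-product self-attention over the sequence axis.

    Q, K, V are learned affine maps of the input; d_k equals the model
    (feature) dimension.
    """

    def __init__(self, d_model: int, rng: np.random.Generator, dtype=np.float32) -> None:
        self.d_model = d_model
        self.q_proj = Dense(d_model, d_model, rng, dtype=dtype, name="attn.q")
        self.k_proj = Dense(d_model, d_model, rng, dtype=dtype, name="attn.k")
        self.v_proj = Dense(d_model, d_model, rng, dtype=dtype, name="attn.v")
        self._cache: dict[str, np.ndarray] | None = None

    def parameters(self) -> list[Parameter]:
        return (
            self.q_proj.parameters()
            + self.k_proj.parameters()
            + self.v_proj.parameters()
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self.q_proj.forward(x)
        k = self.k_proj.forward(x)
        v = self.v_proj.forward(x)
        scores = q @ k.transpose(0, 2, 1) / np.sqrt(self.d_model)
        w = softmax(scores, axis=-1).astype(x.dtype)
        out = w @ v
        self._cache = dict(q=q, k=k, v=v, w=w)
        return out

    def attention_weights(self) -> np.ndarray:
        """Attention weight tensor (batch, S, S) of the last forward pass."""
        return self._cache["w"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cc = self._cache
        q, k, v, w = cc["q"], cc["k"], cc["v"], cc["w"]
        dv = w.transpose(0, 2, 1) @ dy
        dw = dy @ v.transpose(0, 2, 1)
        # softmax Jacobian, row-wise
        ds = w * (dw - (dw * w).sum(axis=-1, keepdims=True))
        ds /= np.sqrt(self.d_model)
        dq = ds @ k
        dk = ds.transpose(0, 2, 1) @ q
        return (
            self.q_proj.backward(dq)
            + self.k_proj.backward(dk)
            + self.v_proj.backward(dv)
        )


class MeanPoolSeq:
    """Mean over the sequence axis: (B, S, F) -> (B, F)."""

    def __init__(self) -> None:
        self._s_len = 0

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._s_len = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :] / self._s_len, self._s_len, axis=1)


def softmax_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits, axis=-1)
    n = logits.shape[0]
    loss = -float(np.sum(onehot * np.log(np.maximum(p, 1e-12)))) / n
    grad = ((p - onehot) / n).astype(logits.dtype)
    return loss, grad
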