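"""The full classifier: parallel multi-scale convolution and BiLSTM
branches fused by self-attention.

Data flow for an input batch (B, S, F):

    standardize -> [Block1: multi-scale conv] and/or [Block2: BiLSTM]
                -> feature-axis concatenation (B, S, D)
                -> single-head self-attention (d_k = D)
                -> mean pooling over the sequence axis
                -> FC1 -> FC2 -> linear logits over n_classes

Block1 captures spatial/spectral structure via parallel kernel widths;
Block2 captures temporal dependencies in both directions; the attention
layer re-weights sequence positions of the merged features.  Ablation
variants keep one branch and leave the rest of the pipeline unchanged.
Softmax is applied by the loss and by :meth:`predict_proba`, not stored
in the graph.
"""

from __future__ import annotations

import numpy as np

from ..config import ModelConfig
from .functional import softmax, standardize
from .layers import (
    BiLSTM,
    Dense,
    MeanPoolSeq,
    MultiScaleConv1D,
    Parameter,
    SelfAttention,
    softmax_cross_entropy,
)

__all__ = ["MultiScaleBiLSTMAttention", "build_model"]


class MultiScaleBiLSTMAttention:
    """Multi-scale conv + BiLSTM + attention classifier (NumPy backend)."""

    def __init__(self, config: ModelConfig, input_shape: tuple[int, int],
                 dtype=np.float32) -> None:
        config.validate()
        s_len, n_feat = int(input_shape[0]), int(input_shape[1])
        if s_len < 1 or n_feat < 1:
            raise ValueError(f"input_shape must be positive, got {input_shape}")
        self.config = config
        self.input_shape = (s_len, n_feat)
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)

        self.conv: MultiScaleConv1D | None = None
        self.bilstm: BiLSTM | None = None
        d_model = 0
        if config.ablation in ("full", "block1"):
            self.conv = MultiScaleConv1D(
                n_feat, config.n_filters, list(config.kernel_sizes), rng,
                activation=config.activation, leaky_slope=config.leaky_slope,
                dtype=dtype,
            )
            d_model += self.conv.n_out
        if config.ablation in ("full", "block2"):
            self.bilstm = BiLSTM(n_feat, config.bilstm_units, rng, dtype=dtype)
            d_model += self.bilstm.n_out
        self.d_model = d_model

        self.attention = SelfAttention(d_model, rng, dtype=dtype)
        self.pool = MeanPoolSeq()
        self.fc1 = Dense(d_model, config.fc1_units, rng,
                         activation=config.activation,
                         leaky_slope=config.leaky_slope, dtype=dtype, name="fc1")
        self.fc2 = Dense(config.fc1_units, config.fc2_units, rng,
                         activation=config.activation,
                         leaky_slope=config.leaky_slope, dtype=dtype, name="fc2")
        self.head = Dense(config.fc2_units, config.n_classes, rng,
                          activation=None, dtype=dtype, name="head")

    # -- parameters --------------------------------------------------------

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        if self.conv is not None:
            params += self.conv.parameters()
        if self.bilstm is not None:
            params += self.bilstm.parameters()
        params += self.attention.parameters()
        params += self.fc1.parameters()
        params += self.fc2.parameters()
        params += self.head.parameters()
        return params

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"shape mismatch for {p.name}: {p.value.shape} vs {w.shape}")
            p.value[...] = w

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (B, n_classes) for a raw batch (B, S, F)."""
        x = standardize(np.asarray(x)).astype(self.dtype)
        feats = []
        if self.conv is not None:
            feats.append(self.conv.forward(x))
        if self.bilstm is not None:
            feats.append(self.bilstm.forward(x))
        merged = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=-1)
        att = self.attention.forward(merged)
        pooled = self.pool.forward(att)
        return self.head.forward(self.fc2.forward(self.fc1.forward(pooled)))

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.fc2.backward(d)
        d = self.fc1.backward(d)
        d = self.pool.backward(d)
        d = self.attention.backward(d)
        if self.conv is not None and self.bilstm is not None:
            split = self.conv.n_out
            self.conv.backward(np.ascontiguousarray(d[..., :split]))
            self.bilstm.backward(np.ascontiguousarray(d[..., split:]))
        elif self.conv is not None:
            self.conv.backward(d)
        else:
            self.bilstm.backward(d)

    def train_step(self, x: np.ndarray, onehot: np.ndarray) -> float:
        """Forward + backward on one batch; returns the batch loss.
        Gradients are accumulated; the caller owns zeroing and stepping."""
        logits = self.forward(x)
        loss, grad = softmax_cross_entropy(logits, onehot.astype(logits.dtype))
        self.backward(grad)
        return loss

    # -- inference ---------------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities (rows sum to 1)."""
        x = np.asarray(x)
        out = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start : start + batch_size])
            out.append(softmax(logits, axis=-1))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)


def build_model(config: ModelConfig, input_shape: tuple[int, int]) -> MultiScaleBiLSTMAttention:
    """Assemble a model for (sequence_length, feature_dim) inputs; all
    weight initialization derives from ``config.seed``."""
    return MultiScaleBiLSTMAttention(config, input_shape)


def save_model(model: MultiScaleBiLSTMAttention, path) -> None:
    """Checkpoint: weights as .npz plus a JSON sidecar with the full
    config and input shape (``<path>.json``)."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    arrays = {f"p{idx:03d}": p.value for idx, p in enumerate(model.parameters())}
    np.savez(path, **arrays)
    sidecar = {"config": model.config.to_dict(), "input_shape": list(model.input_shape)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> MultiScaleBiLSTMAttention:
    """Rebuild a model from :func:`save_model` output."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    config = ModelConfig.from_dict(sidecar["config"])
    model = MultiScaleBiLSTMAttention(config, tuple(sidecar["input_shape"]))
    with np.load(path) as f:
        model.set_weights([f[k] for k in sorted(f.files)])
    return model
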