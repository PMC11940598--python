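"""Model/training configuration with YAML round-trip.

The defaults are the published hyperparameter set of the architecture:
two conv scales (widths 1 and 3) of 32 filters each, BiLSTM with 32
units per direction, FC layers of 64 and 32 units, ReLU activations,
Adam at 0.001 for 100 epochs with batch size 1024, categorical
cross-entropy, seed 42.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["ModelConfig"]

_ABLATIONS = ("full", "block1", "block2")


@dataclass(frozen=True)
class ModelConfig:
    n_filters: int = 32
    kernel_sizes: tuple[int, ...] = (1, 3)
    activation: str = "relu"
    leaky_slope: float = 0.01
    bilstm_units: int = 32
    fc1_units: int = 64
    fc2_units: int = 32
    n_classes: int = 3
    epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 1024
    optimizer: str = "adam"
    loss: str = "categorical_cross_entropy"
    seed: int = 42
    ablation: str = "full"

    def validate(self) -> None:
        if not self.kernel_sizes or any(int(k) < 1 for k in self.kernel_sizes):
            raise ValueError(f"kernel_sizes must be non-empty, all >= 1: {self.kernel_sizes}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        for name in ("n_filters", "bilstm_units", "fc1_units", "fc2_units"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.learning_rate < 0:
            raise ValueError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError(f"activation must be 'relu' or 'leaky_relu', got {self.activation!r}")
        if self.ablation not in _ABLATIONS:
            raise ValueError(f"ablation must be one of {_ABLATIONS}, got {self.ablation!r}")
        if self.optimizer != "adam":
            raise ValueError(f"only the 'adam' optimizer is supported, got {self.optimizer!r}")
        if self.loss != "categorical_cross_entropy":
            raise ValueError(f"only 'categorical_cross_entropy' loss is supported, got {self.loss!r}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel_sizes"] = list(self.kernel_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "kernel_sizes" in d:
            d["kernel_sizes"] = tuple(int(k) for k in d["kernel_sizes"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def replace(self, **kwargs) -> "ModelConfig":
        cfg = replace(self, **kwargs)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        """Short stable digest identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
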