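import numpy as np
import pytest

from eegfuse import ModelConfig, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    """Small learnable 3-class dataset spec shared by fast tests."""
    return SyntheticSpec(
        n_subjects=4,
        n_videos_per_subject=2,
        n_segments_per_video=30,
        n_channels=6,
        window_length=64,
        sampling_rate=128.0,
        n_classes=3,
        snr=5.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture()
def fast_config() -> ModelConfig:
    """Down-scaled model for smoke training in unit tests."""
    return ModelConfig(
        n_filters=4,
        bilstm_units=4,
        fc1_units=8,
        fc2_units=4,
        epochs=2,
        batch_size=64,
        seed=42,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
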