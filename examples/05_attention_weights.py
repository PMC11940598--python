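"""Peek at the attention weights of a trained model.

The attention layer assigns each sequence position a probability
distribution over all positions; rows always sum to 1.  On this
synthetic data the weights show which time points of the merged
conv/BiLSTM features the classifier leans on.
"""

import numpy as np

from eegfuse import ModelConfig, SyntheticSpec, generate_dataset, train

spec = SyntheticSpec(
    n_subjects=3, n_videos_per_subject=1, n_segments_per_video=60,
    n_channels=6, window_length=64, sampling_rate=128.0, snr=5.0, seed=1,
)
data = generate_dataset(spec)
run = train(data, ModelConfig(epochs=5, batch_size=64, seed=42))

model = run.final_model
model.forward(data.samples[:4])
weights = model.attention.attention_weights()  # (batch, S, S)

print(f"attention weights shape: {weights.shape}")
print(f"row sums (first sample, first 5 rows): "
      f"{np.round(weights[0, :5].sum(axis=1), 6)}")
entropy = -(weights[0] * np.log(weights[0] + 1e-12)).sum(axis=1)
print(f"mean row entropy: {entropy.mean():.3f} nats "
      f"(uniform would be {np.log(weights.shape[-1]):.3f})")
# Entropy below the uniform bound means attention concentrates on a
# subset of positions rather than averaging everything equally.
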