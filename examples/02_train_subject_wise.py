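"""Train the full model and evaluate it subject-wise.

The split holds out whole subjects (here 1 of 5), so the reported
metrics measure generalization to unseen individuals — the leakage-safe
protocol.  Takes about a minute on one CPU.
"""

from eegfuse import ModelConfig, SyntheticSpec, generate_dataset, single_test

spec = SyntheticSpec(
    n_subjects=5, n_videos_per_subject=2, n_segments_per_video=200,
    n_channels=8, window_length=64, sampling_rate=128.0,
    n_classes=3, snr=5.0, seed=42,
)
data = generate_dataset(spec)

config = ModelConfig(epochs=20, seed=42)  # published defaults, fewer epochs
report = single_test(data, config)

print(f"held-out subjects:  {report.n_samples} samples")
for name in ("accuracy", "precision", "recall", "f1", "mcc"):
    print(f"  {name:9s} {getattr(report, name):.4f}")
# Values near 1.0 mean the network recovered the class-specific spectral
# structure and transferred it to subjects it never saw during training.
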