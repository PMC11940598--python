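# Methods

## Model

The classifier processes a standardized EEG segment `X ∈ R^{S×F}`
(sequence of S time points over F channels) through two parallel
feature extractors whose outputs are fused by attention.

**Input normalization.** Each sample is standardized per feature
channel along the sequence axis: subtract the mean, divide by the
population SD plus `ε = 1e-8`. Constant channels map to zeros. This
removes per-segment and per-subject amplitude offsets before any
learned parameters see the data.

**Block1 — multi-scale convolution.** One 1-D convolution branch per
kernel width (defaults {1, 3}), each with 32 filters, zero-padded so
the sequence length is preserved, followed by the configured activation
(ReLU by default; Leaky ReLU with slope `a = 0.01` selectable — the
width-1 branch is then a position-wise affine map, the width-3 branch a
local smoother). Branch outputs are concatenated on the feature axis.

**Block2 — bidirectional LSTM.** Standard LSTM gate recurrences
(`σ` forget/input/output gates, `tanh` candidate, elementwise cell
update) run forward and backward over the sequence from zero initial
states; the two hidden streams are concatenated per step (32 units per
direction → 64 features). The vectorized training implementation is
pinned to a per-step scalar reference implementation by test.

**Attention fusion.** The per-step concatenation of both branches
(`D = 128` features with the defaults) is mapped by three learned
affine layers to queries, keys and values; scaled dot-product attention
`softmax(QKᵀ/√d_k)·V` with `d_k = D` re-weights sequence positions.
Single-head self-attention over the *sequence* axis was chosen: the
alternative reading (attention over electrode channels) is available
indirectly via the `"instant"` data layout, in which the sequence axis
enumerates channels. Mean pooling over the sequence follows, keeping
the parameter count independent of S.

**Head.** FC(64) → FC(32), each with the configured activation, then a
linear map to class logits. Softmax is applied by the loss and by
`predict_proba`. Ablation variants `block1` / `block2` drop the other
branch and leave everything else unchanged; they are strict parameter
subsets of the full model.

## Training

Categorical cross-entropy on one-hot labels, minimized with Adam
(moments 0.9/0.999, ε = 1e-8; only the learning rate is configurable,
default 0.001). Defaults: 100 epochs, batch size 1024, seed 42. All
stochastic elements — weight initialization (Glorot-uniform) and the
per-epoch shuffle — derive from `ModelConfig.seed` via a seed sequence,
so runs are bit-reproducible on a fixed platform. No early stopping by
default; an optional validation fraction records held-out loss per
epoch. Forward/backward passes are computed in float32; every layer's
backward pass is validated against central differences in float64.

## Evaluation protocols

- **Single subject-wise test:** `round(0.8 · n_subjects)` subjects
  train (12/3 at the 15-subject geometry), the rest test; subject sets
  are disjoint by construction and asserted on every run. This is the
  leakage-safe protocol: EEG from one individual is strongly dependent
  across time, so pooled splits overstate accuracy.
- **k-fold CV (default k = 10):** class-stratified folds over pooled
  samples, mirroring the common practice; subject-grouped folds are
  available via `grouped=True` and are the recommended variant whenever
  subject generalization is the claim, since stratified pooled folds
  place the same individual on both sides.
- **Ablation:** the three variants are cross-validated on *identical*
  fold assignments (computed once per run) so differences reflect
  architecture only.
- **Random search:** uniform seeded draws from lists of candidate
  values per config field, scored by mean CV accuracy; the argmax
  config and the full trial log are returned.

## Metrics

Accuracy, precision, recall, F1 and MCC from an explicit K×K confusion
matrix. Precision/recall/F1 are defined per class one-vs-rest and
aggregated with support weighting by default (macro selectable); on
balanced data the two coincide, matching the printed
accuracy ≈ precision ≈ recall pattern typical of balanced corpora. MCC
uses the K-class generalization from the full matrix (covariance of
truth/prediction indicators), which reduces exactly to the binary
`(TP·TN − FP·FN)/√(...)` formula at K = 2. Any zero denominator
contributes 0; both conventions are tested, including a 1e-9 agreement
check against scikit-learn over random label vectors.

## Synthetic data generator

The generator emulates the *geometry* of the SEED-family emotion
corpora — `n_subjects × n_videos × n_segments` labeled segments,
balanced classes, 62 channels at 200 Hz by default — with a
class-conditional spectral model:

- each class owns a frequency band (defaults 4–8 / 12–18 / 25–35 Hz for
  3 classes; a 4-band layout for 4 classes);
- a segment is a Hann-windowed sinusoidal burst at a frequency drawn
  uniformly from its class band, projected to channels with positive
  random gains, plus background noise (1/f-shaped "pink" noise from
  spectrally filtered white noise, mixed with white noise at 2:1 SD);
- `snr` sets the ratio of mean signal power to unit noise power
  (default 5, a deliberately strong signal: the benchmark is meant to
  be learnable so that pipeline failures are attributable to code, not
  task difficulty);
- per-subject heterogeneity: a multiplicative gain `1 + N(0, sd)` and
  an additive frequency offset `N(0, sd)` Hz drawn once per subject
  (`subject_effect_sd`, default 0.3). Realized frequencies are clipped
  back into the class band so subject offsets blur, but never break,
  the class structure — this keeps the documented property that ≥95% of
  periodogram peaks fall inside the class band.
- labels are assigned round-robin with a phase that rolls across
  videos, so global per-class counts differ by at most `n_classes − 1`.

What this emulates: balanced labeled segments, spectral class
signatures, inter-subject variability. What it does not: volume
conduction and realistic channel covariance, non-stationarity within
segments, artifacts (blinks, EMG), label noise, or the actual
class-discriminative structure of emotional EEG. Passing tests
therefore demonstrate that the implementation is correct and that the
pipeline can recover planted class structure across subjects — not that
the architecture attains any particular accuracy on real recordings.

## Problem sizes in tests and the acceptance script

Training-based checks run on reduced instances chosen once: 8 channels
and 64-sample windows at 128 Hz, 5 subjects × 2 videos × 200 segments
(20 epochs) for the learnability/leakage check, and 4 subjects × 120
segments with 3 folds (10 epochs) for the ablation comparison. The
ablation runs at 10 epochs because every variant must reach
convergence for the architecture comparison to be meaningful; at much
shorter budgets the larger full model is still mid-descent and the
comparison measures optimization progress instead. Corpus-geometry
counts are computed at full sample counts (225,000 / 360,000) with
small windows, since the counts depend only on the geometry.

## Numerical choices and edge cases

- Zero-denominator metric contributions are 0 (documented and tested).
- `split_by_subject` clamps the train-side subject count to
  `[1, n_subjects − 1]` so both sides are non-empty.
- Softmax and sigmoid use max-shifted / two-branch stable forms.
- Constant channels standardize to zeros via the ε guard.
- The MAT-directory loader cuts contiguous non-overlapping windows from
  trial onset, capped at the requested count — an explicit approximation
  of an unspecified segmentation policy — and shifts the label codes so
  the smallest becomes class 0 (the −1/0/1 convention maps to 0/1/2).

## Known limitations

- Single-head attention with `d_k = D` is one reasonable reading of an
  under-specified fusion layer; multi-head variants are out of scope.
- The NumPy backend targets clarity and reproducibility over speed; it
  is single-device and processes sequences step-by-step in the LSTM.
- Bit-level determinism holds for a fixed platform/BLAS; across
  different BLAS builds results agree only to floating-point tolerance.
- Published headline accuracies on the restricted emotion corpora are
  not reproducible here by construction; the synthetic benchmark bounds
  correctness, not real-data performance.
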