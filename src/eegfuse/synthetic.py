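"""Synthetic EEG-like dataset generator with SEED-style geometry.

The generator emulates the shape of affective-EEG corpora (subjects x
videos x segments, balanced class labels) and plants class-conditional
spectral structure: each class owns a frequency band, and each segment
carries a windowed sinusoidal burst whose frequency is drawn from its
class band, on top of pink + white background noise.  Per-subject gain
and frequency offsets emulate inter-subject variability.  Nothing here
attempts physiological realism (no forward model, no artifacts); the
goal is a dataset on which every downstream stage — subject-wise
splitting, training, metrics — is exercisable and whose classes are
learnable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SyntheticSpec", "EEGWindowSet", "generate_dataset", "split_by_subject"]

#: Default per-class frequency bands (Hz): theta, low beta, high beta/gamma.
DEFAULT_BANDS_3 = ((4.0, 8.0), (12.0, 18.0), (25.0, 35.0))
DEFAULT_BANDS_4 = ((4.0, 8.0), (10.0, 14.0), (18.0, 24.0), (28.0, 36.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset; equal specs give bit-identical data.

    ``subject_effect_sd`` controls both the per-subject amplitude factor
    (multiplicative, ``1 + N(0, sd)``) and the per-subject frequency
    offset (additive, ``N(0, sd)`` Hz).  Realized burst frequencies are
    clipped back into the class band, so subject offsets blur but never
    destroy the class-band structure.
    """

    n_subjects: int = 15
    n_videos_per_subject: int = 15
    n_segments_per_video: int = 1000
    n_channels: int = 62
    window_length: int = 200
    sampling_rate: float = 200.0
    n_classes: int = 3
    class_bands: tuple[tuple[float, float], ...] | None = None
    snr: float = 5.0
    subject_effect_sd: float = 0.3
    seed: int = 0

    def resolved_bands(self) -> tuple[tuple[float, float], ...]:
        if self.class_bands is not None:
            return tuple(tuple(map(float, b)) for b in self.class_bands)
        if self.n_classes == 3:
            return DEFAULT_BANDS_3
        if self.n_classes == 4:
            return DEFAULT_BANDS_4
        raise ValueError(
            "class_bands must be given explicitly when n_classes is not 3 or 4"
        )

    def validate(self) -> None:
        for name in (
            "n_subjects",
            "n_videos_per_subject",
            "n_segments_per_video",
            "n_channels",
            "window_length",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.snr <= 0:
            raise ValueError(f"snr must be > 0, got {self.snr}")
        if self.subject_effect_sd < 0:
            raise ValueError(
                f"subject_effect_sd must be >= 0, got {self.subject_effect_sd}"
            )
        bands = self.resolved_bands()
        if len(bands) != self.n_classes:
            raise ValueError(
                f"class_bands must have exactly n_classes={self.n_classes} entries, "
                f"got {len(bands)}"
            )
        nyquist = self.sampling_rate / 2.0
        for i, (lo, hi) in enumerate(bands):
            if not (0.0 < lo < hi < nyquist):
                raise ValueError(
                    f"class_bands[{i}]=({lo}, {hi}) must be a non-degenerate interval "
                    f"inside (0, {nyquist}) Hz"
                )

    @property
    def n_samples(self) -> int:
        return self.n_subjects * self.n_videos_per_subject * self.n_segments_per_video


@dataclass
class EEGWindowSet:
    """Labeled multichannel EEG segments with subject provenance.

    ``samples`` is (n_samples, sequence_length, feature_dim).  With the
    default ``layout_tag="window"`` the sequence axis is time and the
    feature axis is channels; ``"instant"`` means each sample is a
    channel sequence of scalars (feature_dim 1).
    """

    samples: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    class_names: list[str] = field(default_factory=list)
    sampling_rate: float = 200.0
    layout_tag: str = "window"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subjects = np.asarray(self.subjects)
        if self.samples.ndim != 3:
            raise ValueError(
                f"samples must be 3-D (n, sequence, features), got shape {self.samples.shape}"
            )
        n = self.samples.shape[0]
        if self.labels.shape != (n,) or self.subjects.shape != (n,):
            raise ValueError(
                "samples, labels and subjects must share their first dimension: "
                f"{n}, {self.labels.shape}, {self.subjects.shape}"
            )
        if not self.class_names:
            k = int(self.labels.max()) + 1 if n else 0
            self.class_names = [f"class_{i}" for i in range(k)]
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels must lie in [0, n_classes)")
        if self.layout_tag not in ("window", "instant"):
            raise ValueError(f"layout_tag must be 'window' or 'instant', got {self.layout_tag!r}")
        if n and not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def sequence_length(self) -> int:
        return self.samples.shape[1]

    @property
    def feature_dim(self) -> int:
        return self.samples.shape[2]

    def subject_ids(self) -> np.ndarray:
        return np.unique(self.subjects)

    def select(self, mask: np.ndarray) -> "EEGWindowSet":
        """Row subset sharing metadata (boolean mask or index array)."""
        return EEGWindowSet(
            samples=self.samples[mask],
            labels=self.labels[mask],
            subjects=self.subjects[mask],
            class_names=list(self.class_names),
            sampling_rate=self.sampling_rate,
            layout_tag=self.layout_tag,
        )

    def as_instant(self) -> "EEGWindowSet":
        """Reshape windows to the 'instant' layout: channel sequence of scalars.

        Each time point of each window becomes its own sample whose
        sequence axis runs over channels.  Only sensible for small sets.
        """
        if self.layout_tag == "instant":
            return self
        n, s, f = self.samples.shape
        flat = self.samples.transpose(0, 1, 2).reshape(n * s, f, 1)
        return EEGWindowSet(
            samples=flat,
            labels=np.repeat(self.labels, s),
            subjects=np.repeat(self.subjects, s),
            class_names=list(self.class_names),
            sampling_rate=self.sampling_rate,
            layout_tag="instant",
        )


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_time: int) -> np.ndarray:
    """Approximate 1/f noise: shape white noise by 1/sqrt(f) in frequency."""
    white = rng.standard_normal(shape + (n_time,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_time, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0  # drop DC
    pink = np.fft.irfft(spec * scale, n=n_time, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    return pink / np.maximum(sd, 1e-12)


def generate_dataset(spec: SyntheticSpec) -> EEGWindowSet:
    """Generate a labeled synthetic dataset per ``spec``.

    Labels are assigned round-robin over segments within each video, so
    per-class counts are balanced up to a remainder of at most
    ``n_classes - 1`` per video.  All randomness derives from
    ``spec.seed``: identical specs produce bit-identical datasets.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bands = np.asarray(spec.resolved_bands())
    n_sub, n_vid, n_seg = (
        spec.n_subjects,
        spec.n_videos_per_subject,
        spec.n_segments_per_video,
    )
    n_time, n_ch = spec.window_length, spec.n_channels
    t = np.arange(n_time) / spec.sampling_rate
    envelope = np.hanning(n_time) if n_time > 1 else np.ones(1)

    # Per-subject heterogeneity, drawn once per subject.
    subj_gain = 1.0 + rng.normal(0.0, spec.subject_effect_sd, size=n_sub)
    subj_gain = np.clip(subj_gain, 0.2, None)
    subj_freq_offset = rng.normal(0.0, spec.subject_effect_sd, size=n_sub)

    samples = np.empty((spec.n_samples, n_time, n_ch), dtype=np.float64)
    labels = np.empty(spec.n_samples, dtype=np.int64)
    subjects = np.empty(spec.n_samples, dtype=np.int64)

    row = 0
    for s in range(n_sub):
        for _v in range(n_vid):
            # round-robin labels; the phase rolls across videos so the
            # global per-class counts stay balanced up to n_classes - 1
            lab = (row + np.arange(n_seg)) % spec.n_classes
            lo, hi = bands[lab, 0], bands[lab, 1]
            freq = rng.uniform(lo, hi) + subj_freq_offset[s]
            freq = np.clip(freq, lo, hi)  # keep class-band structure intact
            phase = rng.uniform(0.0, 2 * np.pi, size=n_seg)
            # burst: Hann-windowed sinusoid, (n_seg, n_time)
            burst = np.sin(2 * np.pi * freq[:, None] * t[None, :] + phase[:, None])
            burst *= envelope[None, :]
            # positive per-channel projection keeps the mean-over-channels signal
            chan_gain = rng.uniform(0.5, 1.5, size=(n_seg, n_ch))
            signal = burst[:, :, None] * chan_gain[:, None, :] * subj_gain[s]
            # unit-power background: pink + white mixture
            pink = _pink_noise(rng, (n_seg, n_ch), n_time).transpose(0, 2, 1)
            whit = rng.standard_normal((n_seg, n_time, n_ch))
            noise = pink + 0.5 * whit
            noise /= np.sqrt((noise**2).mean(axis=(1, 2), keepdims=True))
            # scale signal so mean signal power / noise power == snr
            sig_pow = (signal**2).mean(axis=(1, 2), keepdims=True)
            signal *= np.sqrt(spec.snr / np.maximum(sig_pow, 1e-30))
            samples[row : row + n_seg] = signal + noise
            labels[row : row + n_seg] = lab
            subjects[row : row + n_seg] = s
            row += n_seg

    return EEGWindowSet(
        samples=samples,
        labels=labels,
        subjects=subjects,
        class_names=[f"class_{i}" for i in range(spec.n_classes)],
        sampling_rate=spec.sampling_rate,
        layout_tag="window",
    )


def split_by_subject(
    data: EEGWindowSet, train_fraction: float, seed: int
) -> tuple[EEGWindowSet, EEGWindowSet]:
    """Partition samples so no subject appears on both sides.

    The train side receives ``round(train_fraction * n_subjects)``
    subjects (clamped so both sides are non-empty); subject assignment
    is a seeded permutation.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    subject_ids = data.subject_ids()
    n = len(subject_ids)
    if n < 2:
        raise ValueError(f"need at least 2 distinct subjects to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.clip(round(train_fraction * n), 1, n - 1))
    train_subjects = set(subject_ids[order[:n_train]].tolist())
    mask = np.array([s in train_subjects for s in data.subjects.tolist()])
    return data.select(mask), data.select(~mask)
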