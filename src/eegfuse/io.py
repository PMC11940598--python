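"""Dataset persistence and ingestion.

The on-disk container is a single HDF5 file with arrays ``samples``,
``labels`` and ``subjects`` plus a JSON manifest attribute (class names,
sampling rate, layout tag, provenance, format version).  An optional
loader ingests directories of MATLAB recordings laid out like the SEED
emotion corpora (one MAT file per subject with one channels x time
array per video, and a ``label.mat`` with the per-video class codes);
it is exercised in tests only through a tiny fabricated fixture.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import EEGWindowSet

__all__ = [
    "FORMAT_VERSION",
    "DatasetManifest",
    "write_dataset",
    "read_dataset",
    "export_labels_csv",
    "load_seed_directory",
]

FORMAT_VERSION = "1"
_PROVENANCES = ("synthetic", "seed", "seed_iv", "external")


@dataclass
class DatasetManifest:
    """Provenance and geometry record stored alongside the arrays."""

    layout_tag: str
    n_samples: int
    n_classes: int
    class_names: list[str]
    sampling_rate: float
    provenance: str = "synthetic"
    source: dict = field(default_factory=dict)
    format_version: str = FORMAT_VERSION
    path: str = ""

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError(f"n_samples must be positive, got {self.n_samples}")
        if len(self.class_names) != self.n_classes:
            raise ValueError(
                f"class_names has {len(self.class_names)} entries, expected "
                f"n_classes={self.n_classes}"
            )
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"provenance must be one of {_PROVENANCES}")
        if not self.format_version:
            raise ValueError("format_version must be present")

    @classmethod
    def for_dataset(cls, data: EEGWindowSet, provenance: str = "synthetic",
                    source: dict | None = None) -> "DatasetManifest":
        return cls(
            layout_tag=data.layout_tag,
            n_samples=data.n_samples,
            n_classes=data.n_classes,
            class_names=list(data.class_names),
            sampling_rate=float(data.sampling_rate),
            provenance=provenance,
            source=source or {},
        )


def write_dataset(data: EEGWindowSet, manifest: DatasetManifest, path: str | Path) -> Path:
    """Write the HDF5 container; the manifest must match the data."""
    manifest.validate()
    if manifest.n_samples != data.n_samples:
        raise ValueError(
            f"manifest.n_samples={manifest.n_samples} does not match data "
            f"({data.n_samples} samples)"
        )
    if manifest.layout_tag != data.layout_tag or manifest.n_classes != data.n_classes:
        raise ValueError("manifest layout/class metadata does not match the dataset")
    path = Path(path)
    manifest.path = str(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=data.samples)
        f.create_dataset("labels", data=data.labels.astype(np.int64))
        f.create_dataset("subjects", data=data.subjects.astype(np.int64))
        f.attrs["manifest"] = json.dumps(asdict(manifest))
    return path


def read_dataset(path: str | Path) -> tuple[EEGWindowSet, DatasetManifest]:
    """Read a container written by :func:`write_dataset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with h5py.File(path, "r") as f:
        raw = json.loads(f.attrs["manifest"])
        if raw.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported dataset format_version {raw.get('format_version')!r}; "
                f"this reader supports {FORMAT_VERSION!r}"
            )
        manifest = DatasetManifest(**raw)
        data = EEGWindowSet(
            samples=f["samples"][...],
            labels=f["labels"][...],
            subjects=f["subjects"][...],
            class_names=list(manifest.class_names),
            sampling_rate=manifest.sampling_rate,
            layout_tag=manifest.layout_tag,
        )
    return data, manifest


def export_labels_csv(data: EEGWindowSet, path: str | Path) -> Path:
    """Write one row per sample (index, label, class name, subject)."""
    path = Path(path)
    pd.DataFrame(
        {
            "sample": np.arange(data.n_samples),
            "label": data.labels,
            "class_name": [data.class_names[i] for i in data.labels],
            "subject": data.subjects,
        }
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# MAT ingestion (SEED-style directory layout)

_TRIAL_KEY = re.compile(r"^[A-Za-z_0-9]*?(\d+)$")


def _load_mat(path: Path) -> dict:
    """Read classic or HDF5-based MAT files into a dict of arrays."""
    from scipy.io import loadmat

    try:
        raw = loadmat(path)
        return {k: np.asarray(v) for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:  # MAT v7.3 is an HDF5 file
        out = {}
        with h5py.File(path, "r") as f:
            for k in f:
                out[k] = np.asarray(f[k]).T  # v7.3 stores transposed
        return out


def load_seed_directory(
    path: str | Path,
    dataset_kind: str = "seed",
    segments_per_video: int = 1000,
    window_length: int = 200,
    sampling_rate: float = 200.0,
) -> EEGWindowSet:
    """Assemble an :class:`EEGWindowSet` from a SEED-style directory.

    Each subject MAT file must hold one 2-D (channels x time) array per
    video, keyed ``<anything><trial-number>``; ``label.mat`` holds the
    per-video class codes (minimum code is shifted to class 0, so the
    -1/0/1 convention maps to 0/1/2).  From each video,
    ``segments_per_video`` contiguous non-overlapping windows of
    ``window_length`` samples are cut from trial onset — an explicit,
    documented approximation of an unspecified segmentation.  Nothing is
    downloaded; the directory must exist locally.
    """
    if dataset_kind not in ("seed", "seed_iv"):
        raise ValueError(f"dataset_kind must be 'seed' or 'seed_iv', got {dataset_kind!r}")
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"not a directory: {root}")
    label_file = root / "label.mat"
    subject_files = sorted(p for p in root.glob("*.mat") if p.name != "label.mat")
    missing = [str(p) for p in [label_file] if not p.exists()]
    if missing or not subject_files:
        raise FileNotFoundError(
            f"missing required files in {root}: "
            f"{missing or 'no per-subject .mat files found'}"
        )
    label_raw = next(iter(_load_mat(label_file).values())).ravel().astype(int)
    video_labels = label_raw - label_raw.min()  # 0-based class codes

    all_samples, all_labels, all_subjects = [], [], []
    for subject_idx, mat_path in enumerate(subject_files):
        arrays = _load_mat(mat_path)
        trials: list[tuple[int, np.ndarray]] = []
        for key, arr in arrays.items():
            m = _TRIAL_KEY.match(key)
            if m and np.ndim(arr) == 2:
                trials.append((int(m.group(1)), arr))
        if not trials:
            raise ValueError(f"{mat_path} contains no 2-D trial arrays")
        trials.sort(key=lambda kv: kv[0])
        for trial_no, arr in trials:
            if trial_no - 1 >= video_labels.size:
                raise ValueError(
                    f"{mat_path}: trial {trial_no} has no entry in label.mat "
                    f"({video_labels.size} labels)"
                )
            n_windows = arr.shape[1] // window_length
            if n_windows < 1:
                raise ValueError(
                    f"{mat_path}: trial {trial_no} shorter than one window "
                    f"({arr.shape[1]} < {window_length} samples)"
                )
            take = min(segments_per_video, n_windows)
            segs = (
                arr[:, : take * window_length]
                .reshape(arr.shape[0], take, window_length)
                .transpose(1, 2, 0)
            )  # (take, time, channels)
            all_samples.append(segs)
            all_labels.append(np.full(take, video_labels[trial_no - 1]))
            all_subjects.append(np.full(take, subject_idx))

    n_classes = int(video_labels.max()) + 1
    names = {
        "seed": ["negative", "neutral", "positive"],
        "seed_iv": ["neutral", "sad", "fear", "happy"],
    }[dataset_kind]
    if len(names) != n_classes:
        names = [f"class_{i}" for i in range(n_classes)]
    return EEGWindowSet(
        samples=np.concatenate(all_samples).astype(np.float64),
        labels=np.concatenate(all_labels),
        subjects=np.concatenate(all_subjects),
        class_names=names,
        sampling_rate=sampling_rate,
        layout_tag="window",
    )
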