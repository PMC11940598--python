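"""eegfuse: multi-scale convolution + BiLSTM + attention classification
of multichannel EEG segments, with a synthetic benchmark generator and a
subject-wise evaluation protocol."""

from .config import ModelConfig
from .evaluation import (
    CVReport,
    TrainRun,
    evaluate,
    kfold_cv,
    random_search,
    run_ablation,
    single_test,
    train,
)
from .io import (
    DatasetManifest,
    export_labels_csv,
    load_seed_directory,
    read_dataset,
    write_dataset,
)
from .metrics import (
    ConfusionTable,
    EvaluationReport,
    compute_metrics,
    confusion,
    mcc,
)
from .nn import build_model, standardize
from .nn.network import MultiScaleBiLSTMAttention
from .synthetic import EEGWindowSet, SyntheticSpec, generate_dataset, split_by_subject

__version__ = "0.1.0"


def normalize_input(data: EEGWindowSet) -> EEGWindowSet:
    """Standardize every sample per feature channel along the sequence
    axis (zero mean, unit SD with an epsilon guard; constant channels
    map to zeros).  Returns a new dataset; the input is untouched."""
    return EEGWindowSet(
        samples=standardize(data.samples),
        labels=data.labels.copy(),
        subjects=data.subjects.copy(),
        class_names=list(data.class_names),
        sampling_rate=data.sampling_rate,
        layout_tag=data.layout_tag,
    )


__all__ = [
    "ModelConfig",
    "CVReport",
    "TrainRun",
    "evaluate",
    "kfold_cv",
    "random_search",
    "run_ablation",
    "single_test",
    "train",
    "DatasetManifest",
    "export_labels_csv",
    "load_seed_directory",
    "read_dataset",
    "write_dataset",
    "ConfusionTable",
    "EvaluationReport",
    "compute_metrics",
    "confusion",
    "mcc",
    "build_model",
    "standardize",
    "normalize_input",
    "MultiScaleBiLSTMAttention",
    "EEGWindowSet",
    "SyntheticSpec",
    "generate_dataset",
    "split_by_subject",
    "__version__",
]
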