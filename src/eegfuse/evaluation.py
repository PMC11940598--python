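"""Training loop and the evaluation protocols.

Two protocols are provided: a single subject-wise test (held-out
individuals, the leakage-safe protocol) and k-fold cross-validation over
pooled samples (stratified by class by default, optionally grouped by
subject, which is the stricter choice for subject-generalization
claims).  An ablation runner compares the full model against its two
single-branch variants under identical fold assignments, and a seeded
random search scores hyperparameter draws by mean CV accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .config import ModelConfig
from .metrics import EvaluationReport, compute_metrics, confusion
from .nn.layers import softmax_cross_entropy
from .nn.network import MultiScaleBiLSTMAttention, build_model
from .nn.optim import Adam
from .synthetic import EEGWindowSet, split_by_subject

__all__ = [
    "TrainRun",
    "CVReport",
    "train",
    "single_test",
    "kfold_cv",
    "run_ablation",
    "random_search",
]

_METRIC_FIELDS = ("accuracy", "precision", "recall", "f1", "mcc")


@dataclass
class TrainRun:
    """Outcome of one training run: per-epoch history plus the model."""

    config: ModelConfig
    history: dict = field(default_factory=dict)
    final_model: MultiScaleBiLSTMAttention | None = None
    rng_seed: int = 0


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.size, n_classes), dtype=np.float32)
    out[np.arange(labels.size), labels] = 1.0
    return out


def train(
    data: EEGWindowSet,
    config: ModelConfig,
    validation_fraction: float = 0.0,
    verbose: bool = False,
) -> TrainRun:
    """Minimize categorical cross-entropy with Adam.

    All stochastic elements — weight initialization and the per-epoch
    shuffle stream — derive from ``config.seed``, so identical data and
    config reproduce the run bit-for-bit.  ``validation_fraction`` > 0
    holds out a seeded sample-wise fraction and records validation loss
    and accuracy per epoch.
    """
    config.validate()
    if data.n_samples == 0:
        raise ValueError("training data is empty")
    classes_present = np.unique(data.labels)
    if classes_present.size < 2:
        raise ValueError("training data must cover at least 2 classes")
    if data.labels.max() >= config.n_classes:
        raise ValueError(
            f"labels reach {data.labels.max()} but config.n_classes={config.n_classes}"
        )

    ss = np.random.SeedSequence(config.seed)
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])

    x, y = data.samples, data.labels
    if validation_fraction > 0.0:
        n_val = int(round(validation_fraction * data.n_samples))
        perm = shuffle_rng.permutation(data.n_samples)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        x_val, y_val = x[val_idx], y[val_idx]
        x, y = x[train_idx], y[train_idx]
    else:
        x_val = y_val = None

    n = x.shape[0]
    onehot = _one_hot(y, config.n_classes)
    model = build_model(config, (data.sequence_length, data.feature_dim))
    opt = Adam(model.parameters(), learning_rate=config.learning_rate)

    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if x_val is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []

    for epoch in range(config.epochs):
        perm = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = x[idx], onehot[idx]
            logits = model.forward(xb)
            loss, grad = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss * idx.size
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(correct / n)
        if x_val is not None:
            proba = model.predict_proba(x_val)
            vl = -float(
                np.mean(np.log(np.maximum(proba[np.arange(y_val.size), y_val], 1e-12)))
            )
            history["val_loss"].append(vl)
            history["val_accuracy"].append(float((proba.argmax(axis=1) == y_val).mean()))
        if verbose:
            msg = f"epoch {epoch + 1}/{config.epochs} loss={history['loss'][-1]:.4f} acc={history['accuracy'][-1]:.4f}"
            print(msg)

    return TrainRun(config=config, history=history, final_model=model,
                    rng_seed=config.seed)


def evaluate(model: MultiScaleBiLSTMAttention, data: EEGWindowSet,
             averaging: str = "weighted") -> EvaluationReport:
    """Five-metric report of ``model`` on ``data``."""
    y_pred = model.predict(data.samples)
    table = confusion(data.labels, y_pred, model.config.n_classes)
    return compute_metrics(table, averaging)


def single_test(
    data: EEGWindowSet,
    config: ModelConfig,
    train_fraction: float = 0.8,
    averaging: str = "weighted",
    return_run: bool = False,
):
    """Single subject-wise evaluation: train on ~80% of subjects,
    report the five metrics on the held-out subjects only."""
    train_set, test_set = split_by_subject(data, train_fraction, seed=config.seed)
    overlap = np.intersect1d(train_set.subject_ids(), test_set.subject_ids())
    if overlap.size:  # defensive: split_by_subject guarantees disjointness
        raise RuntimeError(f"subject leakage between train and test: {overlap}")
    run = train(train_set, config)
    report = evaluate(run.final_model, test_set, averaging)
    return (report, run) if return_run else report


@dataclass
class CVReport:
    """Per-fold reports with mean and SD per metric and the fold map."""

    reports: list[EvaluationReport]
    fold_assignment: np.ndarray
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean:
            for m in _METRIC_FIELDS:
                vals = np.array([getattr(r, m) for r in self.reports])
                self.mean[m] = float(vals.mean())
                self.sd[m] = float(vals.std())

    @property
    def k(self) -> int:
        return len(self.reports)

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "mean": self.mean,
            "sd": self.sd,
            "folds": [r.as_dict() for r in self.reports],
        }


def make_folds(
    data: EEGWindowSet, k: int, grouped: bool = False, seed: int = 0
) -> np.ndarray:
    """Fold index per sample: class-stratified, or subject-grouped."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n = data.n_samples
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples {n}")
    assignment = np.empty(n, dtype=np.int64)
    if grouped:
        n_subjects = data.subject_ids().size
        if k > n_subjects:
            raise ValueError(f"k={k} exceeds the number of subjects {n_subjects}")
        splitter = GroupKFold(n_splits=k)
        splits = splitter.split(np.zeros(n), data.labels, groups=data.subjects)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=int(seed) % (2**32))
        splits = splitter.split(np.zeros(n), data.labels)
    for fold, (_, val_idx) in enumerate(splits):
        assignment[val_idx] = fold
    return assignment


def kfold_cv(
    data: EEGWindowSet,
    config: ModelConfig,
    k: int = 10,
    grouped: bool = False,
    seed: int | None = None,
    folds: np.ndarray | None = None,
    averaging: str = "weighted",
) -> CVReport:
    """k-fold cross-validation: train k models, one validation fold each.

    ``folds`` may carry a precomputed per-sample fold assignment (used by
    the ablation runner to hold folds fixed across model variants).
    """
    if folds is None:
        folds = make_folds(data, k, grouped=grouped,
                           seed=config.seed if seed is None else seed)
    folds = np.asarray(folds)
    if folds.shape != (data.n_samples,):
        raise ValueError("fold assignment must have one entry per sample")
    reports = []
    for fold in range(k):
        val_mask = folds == fold
        if not val_mask.any():
            raise ValueError(f"fold {fold} is empty")
        run = train(data.select(~val_mask), config)
        reports.append(evaluate(run.final_model, data.select(val_mask), averaging))
    return CVReport(reports=reports, fold_assignment=folds)


def run_ablation(
    data: EEGWindowSet,
    config: ModelConfig,
    k: int,
    grouped: bool = False,
    seed: int | None = None,
) -> dict[str, CVReport]:
    """Cross-validate the full model and both single-branch variants
    under identical fold assignments (a controlled comparison)."""
    folds = make_folds(data, k, grouped=grouped,
                       seed=config.seed if seed is None else seed)
    out = {}
    for tag in ("full", "block1", "block2"):
        out[tag] = kfold_cv(data, config.replace(ablation=tag), k, folds=folds)
    return out


def random_search(
    data: EEGWindowSet,
    space: dict[str, list],
    n_trials: int,
    k: int = 3,
    seed: int = 0,
    base_config: ModelConfig | None = None,
) -> tuple[ModelConfig, list[dict]]:
    """Seeded uniform random search scored by mean k-fold CV accuracy.

    ``space`` maps :class:`ModelConfig` field names to candidate value
    lists.  Returns the best config and the full trial log (one dict per
    trial with the sampled parameters and the score).
    """
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("hyperparameter space must be non-empty")
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    base = base_config or ModelConfig()
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    best_idx = -1
    best_score = -np.inf
    names = sorted(space)
    for trial in range(n_trials):
        draw = {name: space[name][int(rng.integers(len(space[name])))] for name in names}
        cfg = base.replace(**draw)
        score = kfold_cv(data, cfg, k, seed=seed).mean["accuracy"]
        log.append({"trial": trial, "params": draw, "score": score})
        if score > best_score:
            best_score, best_idx = score, trial
    best_cfg = base.replace(**log[best_idx]["params"])
    return best_cfg, log
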