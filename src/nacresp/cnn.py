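"""Training and evaluation protocol for the lesion-crop CNN.

Protocol: crops are split 80/20 into training and test sets at the *patient*
level (every crop of a patient, including its rotated copies, lands on one
side), stratified by responder label. The training set is partitioned into
k = 3 patient-level folds; one model is trained per fold on the other two
and validated on the held-out fold, and the reported validation metrics are
the mean (and median) over folds. The held-out 20% test set is scored by the
fold ensemble: the responder probability is the mean softmax output of the
k models, thresholded at 0.5 for sensitivity/specificity/accuracy, with the
AUC computed from the continuous probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crops import LesionCrop
from .nn import ConvNet
from .stats import roc_analysis


@dataclass
class ArchitectureConfig:
    """CNN architecture and optimization settings.

    The convolutional trunk (two 5x5 conv layers of 32 filters, 2x2 max
    pooling, ReLU) and the two-FC-layer head with dropout and a softmax
    cross-entropy loss optimized by Adam are the fixed design; hidden width,
    dropout rate and the optimization budget are free parameters.
    """

    conv_filters: int = 32
    conv_kernel: int = 5
    fc_hidden: int = 256
    dropout_rate: float = 0.5
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 16

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.conv_filters, self.conv_kernel, self.fc_hidden,
               self.epochs, self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ValueError("architecture sizes and rates must be positive")


@dataclass
class EvalMetrics:
    """Classification metrics, percents except the AUC."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    n_test: int
    fold_values: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "n_test": self.n_test,
            "fold_values": self.fold_values,
        }


def _patient_labels(crops: list[LesionCrop]) -> dict[str, bool]:
    labels: dict[str, bool] = {}
    for c in crops:
        if labels.setdefault(c.patient_id, c.responder) != c.responder:
            raise ValueError(f"inconsistent labels for patient {c.patient_id}")
    return labels


def split_train_test(
    crops: list[LesionCrop],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[LesionCrop], list[LesionCrop]]:
    """Patient-level stratified train/test split.

    Test counts per class are ``round((1 - train_fraction) * n_class)`` but
    at least 1, so both classes are always represented in the test set.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = _patient_labels(crops)
    rng = np.random.default_rng(seed)
    test_patients: set[str] = set()
    for cls in (True, False):
        patients = sorted(p for p, r in labels.items() if r is cls)
        if len(patients) < 2:
            raise ValueError(
                f"need at least 2 patients in the {'responder' if cls else 'non-responder'} class")
        n_test = min(max(1, round((1 - train_fraction) * len(patients))), len(patients) - 1)
        order = rng.permutation(len(patients))
        test_patients.update(patients[i] for i in order[:n_test])
    train = [c for c in crops if c.patient_id not in test_patients]
    test = [c for c in crops if c.patient_id in test_patients]
    return train, test


def make_folds(crops: list[LesionCrop], k: int, seed: int) -> list[list[str]]:
    """Partition the patients into k stratified folds (lists of patient ids)."""
    labels = _patient_labels(crops)
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for cls in (True, False):
        patients = sorted(p for p, r in labels.items() if r is cls)
        order = rng.permutation(len(patients))
        for pos, i in enumerate(order):
            folds[pos % k].append(patients[i])
    return folds


def _stack(crops: list[LesionCrop]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([c.pixels for c in crops]).astype(np.float32)
    y = np.array([int(c.responder) for c in crops])
    return X, y


def _threshold_metrics(prob: np.ndarray, y: np.ndarray, threshold: float) -> dict:
    pred = prob >= threshold
    pos, neg = y == 1, y == 0
    sens = 100.0 * float(pred[pos].mean()) if pos.any() else float("nan")
    spec = 100.0 * float((~pred[neg]).mean()) if neg.any() else float("nan")
    acc = 100.0 * float((pred == (y == 1)).mean())
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


def train_crossval(
    train_crops: list[LesionCrop],
    arch: ArchitectureConfig,
    k: int = 3,
    seed: int = 0,
    input_side: int = 64,
) -> tuple[list[ConvNet], EvalMetrics]:
    """Train k fold-models and summarize validation performance.

    Every training patient appears in exactly one validation fold. Each fold
    must contain both classes (its training complement then does too for
    k >= 2); a degenerate fold raises. Returned metrics are fold means, with
    per-fold values (and the fold median AUC) retained in ``fold_values``.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    folds = make_folds(train_crops, k, seed)
    labels = _patient_labels(train_crops)
    for i, fold in enumerate(folds):
        classes = {labels[p] for p in fold}
        if classes != {True, False}:
            raise ValueError(f"fold {i} does not contain both classes")
    models: list[ConvNet] = []
    fold_values = []
    for i, fold in enumerate(folds):
        val_ids = set(fold)
        tr = [c for c in train_crops if c.patient_id not in val_ids]
        va = [c for c in train_crops if c.patient_id in val_ids]
        Xtr, ytr = _stack(tr)
        Xva, yva = _stack(va)
        model = ConvNet(
            input_side=input_side,
            conv_filters=arch.conv_filters,
            conv_kernel=arch.conv_kernel,
            fc_hidden=arch.fc_hidden,
            dropout_rate=arch.dropout_rate,
            seed=seed * 1000 + i,
        )
        model.fit(Xtr, ytr, epochs=arch.epochs, batch_size=arch.batch_size,
                  learning_rate=arch.learning_rate, shuffle_seed=seed * 1000 + 500 + i)
        prob = model.predict_proba(Xva)[:, 1]
        metrics = _threshold_metrics(prob, yva, 0.5)
        metrics["auc"] = roc_analysis(prob, yva == 1).auc
        metrics["n_val"] = len(va)
        fold_values.append(metrics)
        models.append(model)
    mean = {key: float(np.mean([fv[key] for fv in fold_values]))
            for key in ("sensitivity", "specificity", "accuracy", "auc")}
    summary = EvalMetrics(
        sensitivity=mean["sensitivity"], specificity=mean["specificity"],
        accuracy=mean["accuracy"], auc=mean["auc"],
        n_test=sum(fv["n_val"] for fv in fold_values),
        fold_values=fold_values,
    )
    return models, summary


def evaluate(models: list, test_crops: list[LesionCrop],
             threshold: float = 0.5) -> EvalMetrics:
    """Score the held-out test set with the fold ensemble.

    The responder probability of a crop is the mean of the models' softmax
    responder outputs; hard predictions use the given threshold.
    """
    X, y = _stack(test_crops)
    if len(set(y)) < 2:
        raise ValueError("test set must contain both classes")
    prob = np.mean([m.predict_proba(X)[:, 1] for m in models], axis=0)
    metrics = _threshold_metrics(prob, y, threshold)
    auc = roc_analysis(prob, y == 1).auc
    return EvalMetrics(
        sensitivity=metrics["sensitivity"], specificity=metrics["specificity"],
        accuracy=metrics["accuracy"], auc=auc, n_test=len(test_crops),
    )
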