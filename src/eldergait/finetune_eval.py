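"""Supervised fine-tuning and window-level evaluation.

Protocol: subject-wise 75/25 train/test split; within the training portion an
80/20 train/validation split; model selection via stratified, subject-grouped
5-fold cross-validation repeated over three seeds (15 fold results). Training
runs at most 30 epochs with early stopping after five epochs without
validation-loss improvement; the best-validation-loss epoch's weights are
kept. All partitions are subject-wise: no participant's windows ever span two
partitions (asserted, not assumed).

Window-level metrics (accuracy, specificity, recall, precision, F1, reported
as percentages) come from the confusion matrix, optionally computed per
subject and then averaged — the reporting mode used for daily-living
validation studies. The F1 score drives model selection because gait windows
are rare in daily life and accuracy alone would reward the majority class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GroupShuffleSplit, StratifiedGroupKFold

from ._nn import Adam, Tensor, gather_rows, logsumexp_rows, no_grad, param_checksum
from .model_core import GaitModel, softmax_probabilities
from .preprocess import Window

logger = logging.getLogger(__name__)


@dataclass
class WindowDataset:
    """Stacked labeled windows: X (N, 3, 300), y in {0,1}, subject per row."""

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.subjects = np.asarray(self.subjects)
        if not (len(self.X) == len(self.y) == len(self.subjects)):
            raise ValueError("X, y and subjects must have equal lengths")
        if self.y.size and not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be 0 (non-gait) or 1 (gait)")

    @classmethod
    def from_windows(cls, windows: Sequence[Window]) -> "WindowDataset":
        labeled = [w for w in windows if w.label != "unlabeled"]
        return cls(
            X=np.stack([w.samples for w in labeled]) if labeled
            else np.empty((0, 3, 300), np.float32),
            y=np.array([1 if w.label == "gait" else 0 for w in labeled]),
            subjects=np.array([w.subject_id for w in labeled]),
        )

    def subset(self, idx) -> "WindowDataset":
        return WindowDataset(self.X[idx], self.y[idx], self.subjects[idx])

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class SplitPlan:
    test_fraction: float = 0.25
    inner_val_fraction: float = 0.2
    folds: int = 5
    seeds: tuple[int, ...] = (0, 1, 2)


@dataclass
class TrainState:
    max_epochs: int = 30
    patience: int = 5
    min_delta: float = 1e-4
    learning_rate: float = 1e-4
    batch_size: int = 64
    best_val_loss: float = np.inf
    epochs_since_improvement: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class EarlyStopper:
    """Strict-decrease early stopping: stop after ``patience`` epochs without
    a validation-loss improvement of more than ``min_delta``."""

    def __init__(self, patience: int, min_delta: float = 1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.epochs_since_improvement = 0
        self.improved = False

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; True means halt training now."""
        if loss < self.best_loss - self.min_delta:
            self.best_loss = loss
            self.epochs_since_improvement = 0
            self.improved = True
        else:
            self.epochs_since_improvement += 1
            self.improved = False
        return self.epochs_since_improvement >= self.patience


def _assert_no_leakage(subjects: np.ndarray, *index_sets) -> None:
    seen: set = set()
    for idx in index_sets:
        part = set(subjects[idx])
        if part & seen:
            raise AssertionError(f"subject leakage across partitions: {part & seen}")
        seen |= part


def split_subjectwise(dataset: WindowDataset, plan: SplitPlan, seed: int,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(train, val, test) row indices; every subject in exactly one partition."""
    n_subjects = len(set(dataset.subjects))
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for a subject-wise split")
    outer = GroupShuffleSplit(n_splits=1, test_size=plan.test_fraction,
                              random_state=seed)
    rest_idx, test_idx = next(outer.split(dataset.X, dataset.y, dataset.subjects))
    inner = GroupShuffleSplit(n_splits=1, test_size=plan.inner_val_fraction,
                              random_state=seed + 1)
    tr, va = next(inner.split(rest_idx, groups=dataset.subjects[rest_idx]))
    train_idx, val_idx = rest_idx[tr], rest_idx[va]
    _assert_no_leakage(dataset.subjects, train_idx, val_idx, test_idx)
    return train_idx, val_idx, test_idx


def _ce_loss(logits: Tensor, y: np.ndarray) -> Tensor:
    return (logsumexp_rows(logits) - gather_rows(logits, y)).mean()


def _eval_loss(model: GaitModel, ds: WindowDataset, batch_size: int) -> float:
    model.eval()
    total, n = 0.0, 0
    with no_grad():
        for lo in range(0, len(ds), batch_size):
            sl = slice(lo, lo + batch_size)
            logits = model(Tensor(ds.X[sl]))
            total += _ce_loss(logits, ds.y[sl]).item() * (sl.indices(len(ds))[1] - lo)
            n += sl.indices(len(ds))[1] - lo
    return total / max(n, 1)


def predict_dataset(model: GaitModel, X: np.ndarray,
                    batch_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """(predicted labels, gait probabilities) for stacked windows."""
    model.eval()
    preds, probs = [], []
    with no_grad():
        for lo in range(0, len(X), batch_size):
            logits = model(Tensor(X[lo:lo + batch_size])).data
            p = softmax_probabilities(logits)[:, 1]
            probs.append(p)
            preds.append((p >= 0.5).astype(np.int64))
    return np.concatenate(preds), np.concatenate(probs)


def finetune(train: WindowDataset, val: WindowDataset, model: GaitModel,
             state: TrainState | None = None, unfreeze_all: bool = True,
             seed: int = 0) -> tuple[GaitModel, dict]:
    """Supervised training with early stopping; best-epoch weights restored."""
    state = state or TrainState()
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set must contain both classes")
    if unfreeze_all:
        model.encoder.unfreeze()
    else:
        model.encoder.freeze()
    rng = np.random.default_rng(seed)
    opt = Adam(model.trainable_parameters(), lr=state.learning_rate)
    best_state = model.state_dict()
    history = {"train_loss": [], "val_loss": []}
    stopper = EarlyStopper(state.patience, state.min_delta)
    for _ in range(state.max_epochs):
        model.train()
        order = rng.permutation(len(train))
        epoch = []
        for lo in range(0, len(train), state.batch_size):
            idx = order[lo:lo + state.batch_size]
            logits = model(Tensor(train.X[idx]))
            loss = _ce_loss(logits, train.y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch.append(loss.item())
        val_loss = _eval_loss(model, val, state.batch_size)
        history["train_loss"].append(float(np.mean(epoch)))
        history["val_loss"].append(val_loss)
        halt = stopper.update(val_loss)
        if stopper.improved:
            best_state = model.state_dict()
        if halt:
            break
    state.best_val_loss = stopper.best_loss
    state.epochs_since_improvement = stopper.epochs_since_improvement
    model.load_state_dict(best_state)
    return model, history


@dataclass
class MetricsReport:
    accuracy: float
    specificity: float
    recall: float
    precision: float
    f1: float
    confusion: tuple[int, int, int, int]  # (TP, FP, FN, TN)
    per_subject: pd.DataFrame | None = None


def _metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    total = tp + fp + fn + tn
    acc = 100.0 * (tp + tn) / total if total else np.nan
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else np.nan
    rec = 100.0 * tp / (tp + fn) if (tp + fn) else np.nan
    prec = 100.0 * tp / (tp + fp) if (tp + fp) else np.nan
    f1 = (2 * prec * rec / (prec + rec)
          if np.isfinite(prec) and np.isfinite(rec) and (prec + rec) > 0
          else (0.0 if np.isfinite(prec) and np.isfinite(rec) else np.nan))
    return {"accuracy": acc, "specificity": spec, "recall": rec,
            "precision": prec, "f1": f1}


def window_metrics(predictions: np.ndarray, labels: np.ndarray,
                   per_subject: bool = False,
                   subjects: np.ndarray | None = None) -> MetricsReport:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal lengths")
    for arr, name in ((predictions, "predictions"), (labels, "labels")):
        if arr.size and not set(np.unique(arr)) <= {0, 1}:
            raise ValueError(f"{name} must be binary 0/1")
    tn, fp, fn, tp = confusion_matrix(labels, predictions, labels=[0, 1]).ravel()
    overall = _metrics_from_counts(tp, fp, fn, tn)
    per_subject_df = None
    if per_subject:
        if subjects is None:
            raise ValueError("per_subject=True requires a subjects array")
        rows = []
        for sid in pd.unique(subjects):
            m = subjects == sid
            s_tn, s_fp, s_fn, s_tp = confusion_matrix(
                labels[m], predictions[m], labels=[0, 1]).ravel()
            row = _metrics_from_counts(s_tp, s_fp, s_fn, s_tn)
            if not np.isfinite(row["precision"]):
                logger.info("subject %s: precision undefined (no predicted "
                            "positives); excluded from the average", sid)
            rows.append({"subject_id": sid, **row})
        per_subject_df = pd.DataFrame(rows)
        averaged = {k: float(np.nanmean(per_subject_df[k]))
                    for k in ("accuracy", "specificity", "recall",
                              "precision", "f1")}
        overall = averaged
    return MetricsReport(confusion=(int(tp), int(fp), int(fn), int(tn)),
                         per_subject=per_subject_df, **overall)


@dataclass
class CVResult:
    name: str
    fold_f1: list[float]
    mean_f1: float = field(init=False)
    sd_f1: float = field(init=False)

    def __post_init__(self):
        self.mean_f1 = float(np.mean(self.fold_f1))
        self.sd_f1 = float(np.std(self.fold_f1, ddof=1)) if len(self.fold_f1) > 1 else 0.0


def cross_validate(train_set: WindowDataset, plan: SplitPlan,
                   model_factory: Callable[[int], GaitModel],
                   state: TrainState | None = None,
                   name: str = "config") -> CVResult:
    """5-fold x 3-seed CV; folds grouped by subject, stratified by label."""
    n_subjects = len(set(train_set.subjects))
    if n_subjects < plan.folds:
        raise ValueError(f"{n_subjects} subjects < {plan.folds} folds")
    fold_f1: list[float] = []
    for seed in plan.seeds:
        skf = StratifiedGroupKFold(n_splits=plan.folds, shuffle=True,
                                   random_state=seed)
        for tr_idx, va_idx in skf.split(train_set.X, train_set.y,
                                        train_set.subjects):
            _assert_no_leakage(train_set.subjects, tr_idx, va_idx)
            model = model_factory(seed)
            model, _ = finetune(train_set.subset(tr_idx),
                                train_set.subset(va_idx),
                                model, state=state, seed=seed)
            preds, _ = predict_dataset(model, train_set.X[va_idx])
            report = window_metrics(preds, train_set.y[va_idx])
            fold_f1.append(report.f1)
    return CVResult(name=name, fold_f1=fold_f1)


def select_best_config(results: Sequence[CVResult]) -> CVResult:
    """Argmax mean F1; ties broken by lower sd, then lexical config name."""
    if not results:
        raise ValueError("no configurations to select from")
    return sorted(results, key=lambda r: (-r.mean_f1, r.sd_f1, r.name))[0]


def model_checksum(model: GaitModel) -> str:
    return param_checksum(model)
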