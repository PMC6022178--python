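"""Train/test splitting, confusion matrices and classification metrics.

The confusion matrix follows the convention that rows are true postures and
columns predicted postures, in the canonical order (normal, slight
hunchback, severe hunchback).  From it:

    accuracy      = N_true / N_total          (trace over grand total)
    sensitivity_i = TP_i / (TP_i + FN_i)      (row-wise recall)
    precision_i   = TP_i / (TP_i + FP_i)      (column-wise)

Classes absent from the test set (zero row or column sum) report NaN rather
than zero — an undefined rate, not a bad one.  A harness compares the five
trainers on a common dataset, aggregating accuracy, epochs-to-stop and final
MSE over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .labels import POSTURES
from .network import TrainerConfig, init_mlp, predict, train

__all__ = [
    "EvaluationError",
    "ConfusionMatrix",
    "MetricsReport",
    "split",
    "confusion",
    "metrics",
    "compare_trainers",
]


class EvaluationError(ValueError):
    """Invalid evaluation input."""


def split(features: pd.DataFrame, train_frac: float = 0.8, seed: int = 0,
          stratify: bool = False, label_col: str = "label"):
    """Random train/test partition of a feature table.

    Uniform sampling without replacement; ``stratify=True`` splits each class
    separately so class proportions carry over.  The two parts are disjoint
    and exhaustive, and both must be non-empty.
    """
    if not (0 < train_frac < 1):
        raise EvaluationError("train_frac must lie in (0, 1)")
    n = len(features)
    if n == 0:
        raise EvaluationError("cannot split an empty feature table")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx = []
        for _, grp in features.groupby(label_col, sort=True):
            k = int(round(train_frac * len(grp)))
            perm = rng.permutation(len(grp))
            train_idx.extend(grp.index.to_numpy()[perm[:k]])
        mask = features.index.isin(train_idx)
    else:
        k = int(round(train_frac * n))
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:k]] = True
    train_df = features.loc[mask]
    test_df = features.loc[~mask]
    if len(train_df) == 0 or len(test_df) == 0:
        raise EvaluationError(
            f"split {train_frac} of {n} items leaves an empty side")
    return train_df, test_df


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts by (true posture, predicted posture)."""

    counts: np.ndarray
    classes: tuple = POSTURES

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (len(self.classes), len(self.classes)) or np.any(c < 0):
            raise EvaluationError("confusion counts must be a square non-negative matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def confusion(true_labels: Sequence, predicted_labels: Sequence,
              classes: Sequence = POSTURES) -> ConfusionMatrix:
    """Tally a confusion matrix in the fixed class order."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise EvaluationError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise EvaluationError(f"label outside class set: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


@dataclass(frozen=True)
class MetricsReport:
    """Overall accuracy plus per-class sensitivity and precision (NaN if undefined)."""

    accuracy: float
    sensitivity: np.ndarray
    precision: np.ndarray
    classes: tuple = POSTURES

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": {c: float(s) for c, s in zip(self.classes, self.sensitivity)},
            "precision": {c: float(p) for c, p in zip(self.classes, self.precision)},
        }


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class sensitivity (recall) and precision from a confusion matrix."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise EvaluationError("all-zero confusion matrix")
    tp = np.diag(counts).astype(float)
    row = counts.sum(axis=1).astype(float)   # TP + FN
    col = counts.sum(axis=0).astype(float)   # TP + FP
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, tp / row, np.nan)
        prec = np.where(col > 0, tp / col, np.nan)
    return MetricsReport(accuracy=float(tp.sum() / total), sensitivity=sens,
                         precision=prec, classes=cm.classes)


def compare_trainers(features: pd.DataFrame, configs: Sequence[TrainerConfig],
                     seeds: Sequence[int], train_frac: float = 0.8,
                     n_hidden: int = 4, stratify: bool = False,
                     feature_cols: Sequence[str] = ("mean_norm", "std_norm",
                                                    "max_norm", "min_norm"),
                     classes: Sequence = POSTURES) -> pd.DataFrame:
    """Benchmark trainer configurations on a common dataset.

    For every (config, seed) pair: split, train a fresh ``n_hidden``-unit
    network, measure test accuracy, epochs to stop and final training MSE.
    Returns one row per configuration with the median over seeds plus the
    min-max spread; a failed training run records NaNs for that seed rather
    than aborting the table.
    """
    if len(configs) < 1:
        raise EvaluationError("need at least one trainer configuration")
    rows = []
    for cfg in configs:
        acc, epochs, mses, notes = [], [], [], []
        for seed in seeds:
            try:
                tr, te = split(features, train_frac=train_frac, seed=seed,
                               stratify=stratify)
                model = init_mlp(len(feature_cols), n_hidden, len(classes), seed=seed)
                run_cfg = replace(cfg, seed=seed)
                fitted, hist = train(model, tr[list(feature_cols)].to_numpy(),
                                     tr["label"].to_numpy(), run_cfg, classes=classes)
                pred = predict(fitted, te[list(feature_cols)].to_numpy(), classes=classes)
                rep = metrics(confusion(te["label"].to_numpy(), pred, classes=classes))
                acc.append(rep.accuracy)
                epochs.append(hist.n_epochs)
                mses.append(hist.train_mse[-1])
            except Exception as exc:  # record, do not abort the table
                acc.append(np.nan); epochs.append(np.nan); mses.append(np.nan)
                notes.append(f"seed {seed}: {exc}")
        rows.append({
            "algorithm": cfg.algorithm,
            "accuracy": float(np.nanmedian(acc)),
            "iterations": float(np.nanmedian(epochs)),
            "mse": float(np.nanmedian(mses)),
            "accuracy_spread": float(np.nanmax(acc) - np.nanmin(acc)),
            "iterations_spread": float(np.nanmax(epochs) - np.nanmin(epochs)),
            "notes": "; ".join(notes),
        })
    return pd.DataFrame(rows)
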