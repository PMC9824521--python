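"""Scoring: accuracy, per-class recall/precision/F1, cross-validation.

The protocol mirrors the study design: stratified 3-fold cross-validation,
with all resampling and median imputation fitted inside each training fold,
out-of-fold predictions pooled, and

    accuracy = correct / total
    F1_c     = 2 * recall_c * precision_c / (recall_c + precision_c)

computed from the pooled 3x3 confusion matrix (rows = true class, columns
= predicted, class order bad/neutral/good).  F1 is 0 by convention when
recall + precision = 0.  Method-comparison reports average MQ and NQ
accuracies, as in the study's summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import model as model_mod
from .errors import ValidationError
from .model import CLASSES, ResamplingConfig, fit_scheme, predict


def confusion_matrix(y_true, y_pred, classes=CLASSES) -> np.ndarray:
    """Counts[i, j] = rows with true class i predicted as class j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors differ in length")
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def accuracy(y_true, y_pred) -> float:
    """Fraction of correct estimations."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValidationError("cannot score an empty label vector")
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors differ in length")
    return float(np.mean(y_true == y_pred))


def recall_per_class(cm: np.ndarray, classes=CLASSES) -> dict[str, float]:
    """TP / row-sum per class (0 when the class has no true rows)."""
    rows = cm.sum(axis=1)
    return {
        c: (cm[i, i] / rows[i] if rows[i] else 0.0)
        for i, c in enumerate(classes)
    }


def precision_per_class(cm: np.ndarray, classes=CLASSES) -> dict[str, float]:
    """TP / column-sum per class (0 when the class is never predicted)."""
    cols = cm.sum(axis=0)
    return {
        c: (cm[i, i] / cols[i] if cols[i] else 0.0)
        for i, c in enumerate(classes)
    }


def f1_per_class(cm: np.ndarray, classes=CLASSES) -> dict[str, float]:
    """Harmonic mean of recall and precision; 0 when both are 0."""
    rec = recall_per_class(cm, classes)
    prec = precision_per_class(cm, classes)
    out = {}
    for c in classes:
        denom = rec[c] + prec[c]
        out[c] = 2.0 * rec[c] * prec[c] / denom if denom else 0.0
    return out


@dataclass
class EvaluationReport:
    """Pooled out-of-fold scores of one (feature set, question) run."""

    accuracy: float
    confusion: np.ndarray
    recall: dict = field(default_factory=dict)
    precision: dict = field(default_factory=dict)
    f1: dict = field(default_factory=dict)
    support: dict = field(default_factory=dict)
    y_true: np.ndarray | None = None
    y_pred: np.ndarray | None = None


def score(y_true, y_pred) -> EvaluationReport:
    """Assemble a full report from pooled true/predicted labels."""
    cm = confusion_matrix(y_true, y_pred)
    return EvaluationReport(
        accuracy=accuracy(y_true, y_pred),
        confusion=cm,
        recall=recall_per_class(cm),
        precision=precision_per_class(cm),
        f1=f1_per_class(cm),
        support={c: int(cm[i].sum()) for i, c in enumerate(CLASSES)},
        y_true=np.asarray(y_true),
        y_pred=np.asarray(y_pred),
    )


def cross_validate(
    features: pd.DataFrame,
    labels,
    k: int = 3,
    scheme: str = "over_under_bagging",
    config: ResamplingConfig | None = None,
    split_seed: int = 0,
    base_seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold CV with fold-internal resampling and imputation.

    Out-of-fold predictions are pooled over all folds, so every row is
    scored exactly once.  Raises when some training fold lacks a class
    (use a different ``split_seed`` or more data).
    """
    y = np.asarray(labels)
    X = features if isinstance(features, pd.DataFrame) else pd.DataFrame(np.asarray(features))
    classes, counts = np.unique(y, return_counts=True)
    if k == len(y):
        # Leave-one-out: stratification is moot, every training fold keeps
        # all classes as long as no class is a singleton.
        splits = [(np.delete(np.arange(len(y)), i), np.array([i])) for i in range(len(y))]
    else:
        if counts.min() < k:
            raise ValidationError(
                f"class {classes[np.argmin(counts)]!r} has fewer rows than k={k}"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=split_seed)
        splits = list(skf.split(X, y))
    y_pred = np.empty(len(y), dtype=object)
    for train_idx, test_idx in splits:
        y_train = y[train_idx]
        if np.unique(y_train).size < classes.size:
            raise ValidationError(
                "a class is absent from a training fold; change split_seed "
                "or provide more data"
            )
        fitted = fit_scheme(X.iloc[train_idx], y_train, scheme, config, base_seed)
        y_pred[test_idx] = predict(fitted, X.iloc[test_idx])
    return score(y, y_pred)


def compare_methods(
    datasets: dict,
    labels: dict,
    variants=None,
    scheme: str = "over_under_bagging",
    k: int = 3,
    config: ResamplingConfig | None = None,
    split_seed: int = 0,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Evaluate several method variants on identical fold splits.

    Parameters
    ----------
    datasets : {variant: {question: feature DataFrame}}.
    labels : {question: label vector aligned with every variant's rows}.

    Returns
    -------
    table : DataFrame with one column per variant and rows MQ / NQ / mean
        accuracy (the study's summary layout), plus per-class F1 rows.
    reports : {variant: {question: EvaluationReport}} for drill-down.
    """
    variants = list(datasets) if variants is None else list(variants)
    questions = list(labels)
    reports: dict = {}
    for variant in variants:
        reports[variant] = {}
        for q in questions:
            reports[variant][q] = cross_validate(
                datasets[variant][q], labels[q], k=k, scheme=scheme,
                config=config, split_seed=split_seed, base_seed=base_seed,
            )
    rows = {}
    for q in questions:
        rows[f"{q}_accuracy"] = [reports[v][q].accuracy for v in variants]
    rows["mean_accuracy"] = [
        float(np.mean([reports[v][q].accuracy for q in questions])) for v in variants
    ]
    for cls in CLASSES:
        rows[f"f1_{cls}_mean"] = [
            float(np.mean([reports[v][q].f1[cls] for q in questions]))
            for v in variants
        ]
    table = pd.DataFrame(rows, index=variants).T
    return table, reports


def majority_class_rate(labels) -> float:
    """Accuracy of always predicting the most frequent class."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    return float(counts.max() / counts.sum())
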