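"""Percentage-of-positive-activity (PPA) peptide labeling and the
binder/non-binder classification benchmark.

A peptide's PPA is its binding-event count as a percent of the maximum count
over all peptides; activity is 1 iff PPA strictly exceeds a threshold
(default 30 %, the level at which the positive/negative classes are roughly
balanced). Classifiers (SVM with RBF kernel as the primary method, plus
random forest, naive Bayes, a single-hidden-layer neural network and k-NN as
comparators) are evaluated by random subsampling — positives split 4:1
train:test, negatives likewise — and by leave-one-out cross-validation, with
precision, recall, specificity, accuracy, F-measure and AUC per split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .binarize import BinaryBindingMatrix

ALGORITHMS = ("svm_rbf", "random_forest", "naive_bayes", "ann", "knn")


@dataclass
class PPALabels:
    peptide_ids: list[str]
    event_counts: np.ndarray
    ppa: np.ndarray  # percent of the maximum event count
    activity: np.ndarray | None = None
    threshold_percent: float | None = None

    @property
    def n_pos(self) -> int:
        return int(self.activity.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.activity) - self.activity.sum())


def compute_ppa(binary: BinaryBindingMatrix) -> PPALabels:
    """Per-peptide binding-event counts scaled so the busiest peptide is 100 %."""
    counts = binary.bits.sum(axis=0).to_numpy(dtype=float)
    if counts.max() == 0:
        raise ValueError("binding matrix has no binding events")
    return PPALabels(peptide_ids=list(binary.bits.columns),
                     event_counts=counts.astype(int),
                     ppa=100.0 * counts / counts.max())


def assign_activity(labels: PPALabels, threshold_percent: float = 30.0) -> PPALabels:
    """Label activity 1 iff PPA > threshold (strict). Returns a new PPALabels
    carrying the threshold; Table-style statistics via :func:`activity_stats`."""
    if not 0 <= threshold_percent < 100:
        raise ValueError(f"threshold must be in [0, 100), got {threshold_percent}")
    activity = (labels.ppa > threshold_percent).astype(int)
    return PPALabels(peptide_ids=labels.peptide_ids, event_counts=labels.event_counts,
                     ppa=labels.ppa, activity=activity,
                     threshold_percent=threshold_percent)


def activity_stats(labels: PPALabels) -> dict:
    """One dataset-statistics row: threshold, positives, negatives, % positive."""
    if labels.activity is None:
        raise ValueError("assign_activity first")
    n = len(labels.activity)
    return {"threshold_percent": labels.threshold_percent,
            "n_pos": labels.n_pos, "n_neg": labels.n_neg,
            "pct_pos": int(round(100.0 * labels.n_pos / n))}


def subsample_splits(activity: Sequence[int], n_splits: int = 3, seed: int = 0,
                     train_fraction: float = 0.8) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random subsampling splits: each class independently divided
    train:test in ``train_fraction`` (default 4:1) without replacement.

    Returns (train_idx, test_idx) pairs; within a split the two sets
    partition all items. Each class must have >= 5 members.
    """
    y = np.asarray(activity, dtype=int)
    rng = np.random.default_rng(seed)
    pos = np.where(y == 1)[0]
    neg = np.where(y == 0)[0]
    if len(pos) < 5 or len(neg) < 5:
        raise ValueError("each class needs at least 5 members for a 4:1 split")
    splits = []
    for _ in range(n_splits):
        tr, te = [], []
        for grp in (pos, neg):
            perm = rng.permutation(grp)
            k = int(round(train_fraction * len(grp)))
            tr.append(perm[:k])
            te.append(perm[k:])
        splits.append((np.sort(np.concatenate(tr)), np.sort(np.concatenate(te))))
    return splits


def _make_model(algorithm: str, params: dict | None, seed: int):
    p = dict(params or {})
    if algorithm == "svm_rbf":
        return SVC(kernel="rbf", gamma=p.get("gamma", 0.5), C=p.get("C", 2.0),
                   random_state=seed)
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=p.get("n_estimators", 500),
                                      random_state=seed)
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "ann":
        return MLPClassifier(hidden_layer_sizes=(p.get("hidden_units", 10),),
                             activation="logistic", max_iter=p.get("max_iter", 1000),
                             random_state=seed)
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=p.get("k", 5))
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Precision, recall, specificity, accuracy and F-measure from counts.

    Undefined ratios (zero denominators) come back as NaN rather than 0.
    """
    def ratio(a, b):
        return a / b if b else float("nan")
    p = ratio(tp, tp + fp)
    r = ratio(tp, tp + fn)
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "precision": p, "recall": r,
            "specificity": ratio(tn, tn + fp),
            "accuracy": ratio(tp + tn, tp + tn + fp + fn),
            "f_measure": ratio(2 * p * r, p + r) if (p + r) else float("nan")}


@dataclass
class MetricsReport:
    algorithm: str
    per_split: list[dict]
    params: dict = field(default_factory=dict)

    @property
    def averages(self) -> dict:
        keys = ("precision", "recall", "specificity", "accuracy", "f_measure", "auc")
        return {k: float(np.nanmean([s.get(k, np.nan) for s in self.per_split]))
                for k in keys}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_split)


def evaluate(features, activity: Sequence[int],
             splits: Sequence[tuple[np.ndarray, np.ndarray]],
             algorithm: str = "svm_rbf", params: dict | None = None,
             seed: int = 0) -> MetricsReport:
    """Fit on each split's training set, score its test set, and report the
    confusion-matrix metrics plus AUC per split and on average."""
    X = features.to_numpy() if hasattr(features, "to_numpy") else np.asarray(features, float)
    y = np.asarray(activity, dtype=int)
    if X.shape[0] != len(y):
        raise ValueError("features and labels are not row-aligned")
    per_split = []
    for tr, te in splits:
        model = _make_model(algorithm, params, seed)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        yt = y[te]
        row = metrics_from_confusion(
            tp=int(((pred == 1) & (yt == 1)).sum()),
            fp=int(((pred == 1) & (yt == 0)).sum()),
            tn=int(((pred == 0) & (yt == 0)).sum()),
            fn=int(((pred == 0) & (yt == 1)).sum()))
        row["auc"] = (float(roc_auc_score(yt, _scores(model, X[te])))
                      if len(set(yt)) == 2 else float("nan"))
        per_split.append(row)
    return MetricsReport(algorithm=algorithm, per_split=per_split,
                         params=dict(params or {}))


def loocv_evaluate(features, activity: Sequence[int], algorithm: str = "svm_rbf",
                   params: dict | None = None, seed: int = 0) -> MetricsReport:
    """Leave-one-out cross-validation with a pooled confusion matrix (and AUC
    over the pooled held-out scores)."""
    X = features.to_numpy() if hasattr(features, "to_numpy") else np.asarray(features, float)
    y = np.asarray(activity, dtype=int)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 items for LOOCV")
    preds = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = _make_model(algorithm, params, seed)
        model.fit(X[mask], y[mask])
        preds[i] = model.predict(X[i:i + 1])[0]
        scores[i] = _scores(model, X[i:i + 1])[0]
    row = metrics_from_confusion(
        tp=int(((preds == 1) & (y == 1)).sum()),
        fp=int(((preds == 1) & (y == 0)).sum()),
        tn=int(((preds == 0) & (y == 0)).sum()),
        fn=int(((preds == 0) & (y == 1)).sum()))
    row["auc"] = (float(roc_auc_score(y, scores)) if len(set(y)) == 2
                  else float("nan"))
    return MetricsReport(algorithm=algorithm, per_split=[row],
                         params=dict(params or {}))
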