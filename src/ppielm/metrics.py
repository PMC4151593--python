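"""Confusion-matrix metrics, rank-based AUC, ROC curves and stratified CV.

ACC, SN, SP, PPV, NPV, F1 and MCC follow the standard confusion-matrix
definitions.  AUC is computed in Mann-Whitney rank form:

    AUC = (S0 - n0 (n0 + 1) / 2) / (n0 n1)

with S0 the sum of the positive samples' ranks in the score ordering
(average ranks on ties), n0 positives, n1 negatives.  Cross-validation is
stratified k-fold (default 5): each fold holds nearly equal numbers of
interacting and non-interacting pairs; the scaler and model are refitted
inside every fold so no test information leaks into training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from . import elm as elm_mod

METRIC_NAMES = ("ACC", "SN", "SP", "PPV", "NPV", "F1", "MCC", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(predictions: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Tally a binary confusion matrix (1 = positive/interacting)."""
    predictions = np.asarray(predictions).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    return ConfusionCounts(
        TP=int(np.sum(predictions & labels)),
        FP=int(np.sum(predictions & ~labels)),
        TN=int(np.sum(~predictions & ~labels)),
        FN=int(np.sum(~predictions & labels)),
    )


def _ratio(num: float, den: float) -> float:
    # undefined metrics are NaN, never coerced to 0
    return num / den if den > 0 else math.nan


def basic_metrics(c: ConfusionCounts) -> dict[str, float]:
    """ACC, SN, SP, PPV, NPV, F1 and MCC from confusion counts.

    A metric with a zero denominator is reported as NaN.
    """
    tp, fp, tn, fn = c.TP, c.FP, c.TN, c.FN
    acc = _ratio(tp + tn, c.total)
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    if math.isnan(sn) or math.isnan(ppv) or sn + ppv == 0:
        f1 = math.nan
    else:
        f1 = 2 * sn * ppv / (sn + ppv)
    mcc_den = math.sqrt(float(tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan
    return {"ACC": acc, "SN": sn, "SP": sp, "PPV": ppv, "NPV": npv,
            "F1": f1, "MCC": mcc}


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-form AUC (Mann-Whitney): ranks in increasing score order with
    average ranks on ties; requires both classes present."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n0 = int(labels.sum())
    n1 = int((~labels).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC requires both positive and negative samples")
    ranks = rankdata(scores)  # average ranks, increasing order
    s0 = float(ranks[labels].sum())
    return (s0 - n0 * (n0 + 1) / 2) / (n0 * n1)


def roc_points(scores: np.ndarray, labels: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve as (1 - SP, SN) points, one per distinct threshold,
    monotone with endpoints (0, 0) and (1, 1)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0
                     ) -> list[np.ndarray]:
    """Indices of k disjoint stratified folds (shuffled, reproducible)."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class size ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros_like(labels), labels)]


@dataclass
class CvReport:
    """Per-fold metrics plus their mean and sample (n-1) standard deviation."""

    per_fold: list[dict[str, float]] = field(default_factory=list)

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(np.nanmean([f[m] for f in self.per_fold]))
                for m in METRIC_NAMES}

    @property
    def std(self) -> dict[str, float]:
        return {m: float(np.nanstd([f[m] for f in self.per_fold], ddof=1))
                for m in METRIC_NAMES}

    def as_dict(self) -> dict:
        return {"per_fold": self.per_fold, "mean": self.mean, "std": self.std}


def evaluate_scores(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """All eight metrics for continuous scores thresholded at 0."""
    preds = (np.asarray(scores) >= 0).astype(int)
    out = basic_metrics(confusion(preds, labels))
    out["AUC"] = auc_rank(scores, labels)
    return out


def cross_validate(X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0,
                   L: int | str = "auto", activation: str = "sigmoid",
                   ridge: float = 0.0) -> CvReport:
    """Stratified k-fold cross-validation of the ELM pipeline.

    The scaler and the model are refitted on each fold's training split.
    The model seed is derived from ``seed`` per fold so folds use
    independent random hidden layers.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    folds = stratified_kfold(y, k=k, seed=seed)
    report = CvReport()
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        model = elm_mod.fit(X[train_mask], y[train_mask], L=L,
                            activation=activation,
                            seed=(seed * k + i) % (2**31), ridge=ridge)
        scores = elm_mod.decision_scores(model, X[test_idx])
        report.per_fold.append(evaluate_scores(scores, y[test_idx]))
    return report


def holdout_split(labels: np.ndarray, test_fraction: float = 0.2,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A single stratified train/test split (default four-fifths /
    one-fifth), as used for hidden-neuron sizing."""
    k = round(1 / test_fraction)
    test_idx = stratified_kfold(labels, k=k, seed=seed)[0]
    train_mask = np.ones(len(labels), dtype=bool)
    train_mask[test_idx] = False
    return np.flatnonzero(train_mask), test_idx
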