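"""Cross-validated classifier evaluation for binary enzyme classification.

Conventions: the positive class is **alkaline** (coded 1; acid is 0).
Evaluation pools out-of-fold predictions from a seeded stratified k-fold
split into one confusion matrix, from which sensitivity (Sn), specificity
(Sp), accuracy (ACC) and the Matthews correlation coefficient (MCC) are
derived:

    Sn  = TP / (TP + FN)
    Sp  = TN / (FP + TN)
    ACC = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP·TN - FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator is zero (a degenerate fold composition) is
reported as 0 with a warning rather than aborting the run.  Ranking quality
is summarised by the areas under the ROC and precision-recall curves of the
pooled out-of-fold scores.

Two classifier specs mirror the study setup: ``"rf"`` — a random forest
with 100 trees and unlimited depth — and ``"logistic"`` — logistic
regression with only a weak ridge penalty for numerical stability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold


class ConfusionMetrics(NamedTuple):
    sn: float
    sp: float
    acc: float
    mcc: float


@dataclass(frozen=True)
class EvalResult:
    """Pooled cross-validation outcome for one model / feature set."""

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float
    sp: float
    acc: float
    mcc: float
    roc_auc: float
    pr_auc: float
    folds: int
    seed: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    """Sn, Sp, ACC and MCC from confusion counts.

    Counts must be non-negative with a positive total.  Any metric with a
    zero denominator is 0 (with a warning).
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts are all zero")
    sn = _safe_ratio(tp, tp + fn, "sensitivity")
    sp = _safe_ratio(tn, fp + tn, "specificity")
    acc = (tp + tn) / total
    mcc_den_sq = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den_sq == 0:
        warnings.warn("MCC: zero denominator, reporting 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den_sq)
    return ConfusionMetrics(sn=float(sn), sp=float(sp), acc=float(acc), mcc=float(mcc))


def roc_pr_areas(labels, scores) -> tuple[float, float]:
    """Areas under the ROC and precision-recall curves.

    ROC AUC uses the rank statistic (ties counted half); PR AUC is the
    step-wise average precision.  Both classes must be present and all
    scores finite.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return float(roc_auc_score(labels, scores)), float(average_precision_score(labels, scores))


def make_classifier(spec, seed: int = 1) -> BaseEstimator:
    """Instantiate a classifier from a spec string or estimator instance.

    ``"rf"``: RandomForestClassifier(100 trees, unlimited depth, seeded).
    ``"logistic"``: LogisticRegression with a weak ridge (C = 1e4).
    An estimator instance is cloned as-is.
    """
    if isinstance(spec, BaseEstimator):
        return clone(spec)
    if spec == "rf":
        return RandomForestClassifier(n_estimators=100, max_depth=None,
                                      random_state=seed, n_jobs=1)
    if spec == "logistic":
        return LogisticRegression(C=1e4, max_iter=1000)
    raise ValueError(f"unknown classifier spec {spec!r}")


def cross_validate(X, y, model="rf", folds: int = 10, seed: int = 1) -> EvalResult:
    """Stratified k-fold CV with pooled out-of-fold predictions.

    Every instance is predicted exactly once by a model that never saw it;
    the pooled predictions and class-1 scores feed one :class:`EvalResult`.
    Deterministic for a fixed (X, y, model, folds, seed).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    score = np.empty(len(y), dtype=float)
    for train, test in splitter.split(X, y):
        clf = make_classifier(model, seed=seed)
        clf.fit(X[train], y[train])
        pred[test] = clf.predict(X[test])
        score[test] = clf.predict_proba(X[test])[:, list(clf.classes_).index(1)]
    return _evaluate_predictions(y, pred, score, folds, seed)


def _evaluate_predictions(y, pred, score, folds: int, seed: int) -> EvalResult:
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    m = confusion_metrics(tp, tn, fp, fn)
    roc, pr = roc_pr_areas(y, score)
    return EvalResult(tp=tp, tn=tn, fp=fp, fn=fn, sn=m.sn, sp=m.sp, acc=m.acc,
                      mcc=m.mcc, roc_auc=roc, pr_auc=pr, folds=folds, seed=seed)


def single_feature_model(X, y, feature_index: int, folds: int = 10,
                         seed: int = 1) -> EvalResult:
    """Cross-validated logistic regression on a single feature column.

    A constant column carries no signal: the model degenerates to a
    majority vote (accuracy = majority-class rate, chance-level ranking).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    col = X[:, feature_index]
    if np.ptp(col) == 0:
        warnings.warn("constant feature column: falling back to majority vote",
                      stacklevel=2)
        majority = int(np.bincount(y).argmax())
        pred = np.full_like(y, majority)
        score = np.full(len(y), 0.5)
        return _evaluate_predictions(y, pred, score, folds, seed)
    return cross_validate(col[:, None], y, model="logistic", folds=folds, seed=seed)
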