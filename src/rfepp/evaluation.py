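"""Multiclass ROC/AUC machinery, threshold choice and score summaries.

Class imbalance is the norm in clinical cohorts, so the headline score
everywhere is ROC AUC rather than accuracy.  Two multiclass averages are
computed side by side: *micro* (pool every per-class indicator/score
pair into one binary problem — robust to imbalance, the headline test
metric) and *one-vs-one weighted* (mean of pairwise-class AUCs weighted
by prevalence — the score tracked during the elimination loop).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    auc as _trapezoid_auc,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
    roc_curve as _sk_roc_curve,
)
from sklearn.preprocessing import label_binarize


class EvaluationError(ValueError):
    pass


@dataclass
class RocCurve:
    """One ROC curve: (fpr, tpr, threshold) triples plus its AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    averaging: str


def _check_scores(y_true: np.ndarray, scores: np.ndarray, classes: list[str]) -> None:
    if len(set(y_true)) < 2:
        raise EvaluationError("ROC analysis needs at least 2 observed classes")
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise EvaluationError(
            f"score matrix shape {scores.shape} does not match {len(classes)} classes"
        )


def _binarized(y_true: np.ndarray, classes: list[str]) -> np.ndarray:
    onehot = label_binarize(y_true, classes=classes)
    if len(classes) == 2:  # label_binarize collapses binary to one column
        onehot = np.hstack([1 - onehot, onehot])
    return onehot


def roc_curve_and_auc(
    y_true,
    scores,
    averaging: str = "micro",
    classes: list[str] | None = None,
) -> RocCurve | dict[str, RocCurve]:
    """ROC curve(s) and AUC for per-class probability scores.

    ``averaging='micro'`` pools all (indicator, score) pairs across
    classes into one curve; ``'ovo_weighted'`` returns the
    prevalence-weighted mean of pairwise-class AUCs (no single curve, so
    the stored curve is the micro curve with the ovo AUC attached);
    ``'per_class'`` returns one one-vs-rest curve per class.
    """
    y_true = np.asarray(y_true, dtype=object).astype(str)
    scores = np.asarray(scores, dtype=float)
    if classes is None:
        classes = sorted(set(y_true))
    _check_scores(y_true, scores, classes)
    onehot = _binarized(y_true, classes)

    if averaging == "per_class":
        out: dict[str, RocCurve] = {}
        for k, label in enumerate(classes):
            fpr, tpr, thr = _sk_roc_curve(onehot[:, k], scores[:, k])
            out[label] = RocCurve(fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr)), "per_class")
        return out

    fpr, tpr, thr = _sk_roc_curve(onehot.ravel(), scores.ravel())
    micro_auc = float(_trapezoid_auc(fpr, tpr))
    if averaging == "micro":
        return RocCurve(fpr, tpr, thr, micro_auc, "micro")
    if averaging == "ovo_weighted":
        if len(classes) == 2:
            ovo = float(roc_auc_score(y_true, scores[:, 1], labels=classes))
        else:
            ovo = float(
                roc_auc_score(y_true, scores, multi_class="ovo", average="weighted",
                              labels=classes)
            )
        return RocCurve(fpr, tpr, thr, ovo, "ovo_weighted")
    raise EvaluationError(f"unknown averaging {averaging!r}")


def micro_auc(y_true, scores, classes: list[str] | None = None) -> float:
    """Convenience: the pooled micro-averaged ROC AUC."""
    return roc_curve_and_auc(y_true, scores, "micro", classes).auc


def ovo_weighted_auc(y_true, scores, classes: list[str] | None = None) -> float:
    return roc_curve_and_auc(y_true, scores, "ovo_weighted", classes).auc


def optimal_threshold(curve: RocCurve) -> float:
    """Threshold of the ROC point nearest the top-left corner (0, 1).

    The point minimising ``sqrt(fpr^2 + (1 - tpr)^2)`` is the best
    sensitivity/false-positive trade-off; distance ties resolve to the
    lower false-positive rate.
    """
    if curve.fpr.size == 0:
        raise EvaluationError("degenerate ROC curve")
    dist = np.hypot(curve.fpr, 1.0 - curve.tpr)
    order = np.lexsort((curve.fpr, dist))  # primary: distance, tie: lower fpr
    return float(curve.thresholds[order[0]])


@dataclass
class ScoreReport:
    """Confusion matrix and the standard per-class classification scores."""

    classes: list[str]
    confusion: np.ndarray  # rows = true, columns = predicted
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_f1: float
    weighted_f1: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
            }
        )


def confusion_and_scores(y_true, y_pred, classes: list[str] | None = None) -> ScoreReport:
    """Confusion matrix plus accuracy, per-class P/R/F1 and macro/weighted F1.

    Classes absent from the truth get zero scores (with a warning), so
    reports over restricted label subsets stay well defined.
    """
    y_true = np.asarray(y_true, dtype=object).astype(str)
    y_pred = np.asarray(y_pred, dtype=object).astype(str)
    if y_true.size == 0:
        raise EvaluationError("empty evaluation input")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, zero_division=0
        )
    support = np.asarray(support, dtype=float)
    weighted = float((f1 * support).sum() / support.sum()) if support.sum() else 0.0
    return ScoreReport(
        classes=list(classes),
        confusion=confusion_matrix(y_true, y_pred, labels=classes),
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=dict(zip(classes, prec.astype(float))),
        recall=dict(zip(classes, rec.astype(float))),
        f1=dict(zip(classes, f1.astype(float))),
        macro_f1=float(np.mean(f1)),
        weighted_f1=weighted,
    )


def predict_with_threshold(
    scores: np.ndarray,
    classes: list[str],
    thresholds: dict[str, float] | None = None,
) -> np.ndarray:
    """Class predictions from probabilities, honouring per-class thresholds.

    With thresholds, a sample is assigned the passing class of highest
    score margin over its threshold; if no class passes, plain argmax is
    the fallback.  Without thresholds this is argmax.
    """
    scores = np.asarray(scores, dtype=float)
    argmax = np.asarray(classes, dtype=object)[scores.argmax(axis=1)]
    if not thresholds:
        return argmax.astype(str)
    thr = np.array([thresholds.get(c, 0.5) for c in classes])
    margin = scores - thr
    passing = margin.max(axis=1) >= 0
    best = np.asarray(classes, dtype=object)[margin.argmax(axis=1)]
    return np.where(passing, best, argmax).astype(str)


@dataclass
class EvaluationReport:
    """Scores of one model on one split, under both AUC averages."""

    split: str
    micro_auc: float
    ovo_weighted_auc: float
    scores: ScoreReport
    per_class_auc: dict[str, float] = field(default_factory=dict)


def evaluate_split(split: str, y_true, proba, classes: list[str],
                   thresholds: dict[str, float] | None = None) -> EvaluationReport:
    """Full report for one split: both AUC averages + thresholded confusion."""
    y_pred = predict_with_threshold(proba, classes, thresholds)
    per_class = roc_curve_and_auc(y_true, proba, "per_class", classes)
    return EvaluationReport(
        split=split,
        micro_auc=micro_auc(y_true, proba, classes),
        ovo_weighted_auc=ovo_weighted_auc(y_true, proba, classes),
        scores=confusion_and_scores(y_true, y_pred, classes),
        per_class_auc={c: rc.auc for c, rc in per_class.items()},
    )


def score_distributions(scores: dict[str, list[float]]) -> pd.DataFrame:
    """Five-number summary (min, q1, median, q3, max) per score category.

    Input maps a category label (e.g. ``"cv/ovo_weighted"``) to its
    observed scores across iterations/simulations; this is the numeric
    backing of the violin/box performance plots.
    """
    rows = {}
    for name, values in scores.items():
        if len(values) == 0:
            raise EvaluationError(f"no scores for category {name!r}")
        v = np.asarray(values, dtype=float)
        rows[name] = {
            "min": float(v.min()),
            "q1": float(np.quantile(v, 0.25)),
            "median": float(np.quantile(v, 0.5)),
            "q3": float(np.quantile(v, 0.75)),
            "max": float(v.max()),
            "n": int(v.size),
        }
    return pd.DataFrame(rows).T
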