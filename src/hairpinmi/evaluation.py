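"""Classifier evaluation: confusion-matrix metrics, jackknife and k-fold
protocols, ROC/PR curves, information-gain feature ranking, and a feature
subset ablation harness.

Metric conventions: SE = TP/(TP+FN), SP = TN/(TN+FP), PR = TP/(TP+FP),
F1 = 2*SE*PR/(SE+PR), ACC = (TP+TN)/n, and the Matthews correlation
coefficient. A metric whose denominator is zero is reported as 0 and the
result carries a warning flag, so evaluation rounds with a missing class
still aggregate cleanly.

Cross-validation is leakage-free by construction: each round fits the full
estimator (including its feature normalisation) on the training rows only.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import (
    auc as _trapezoid_auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .mi import FEATURE_BLOCKS, FEATURE_NAMES
from .model import HairpinClassifier


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class EvaluationResult:
    counts: ConfusionCounts
    se: float
    sp: float
    pr: float
    f1: float
    acc: float
    mcc: float
    auc: float | None = None
    aupr: float | None = None
    undefined_metrics: tuple[str, ...] = ()
    per_fold: list["EvaluationResult"] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "TP": self.counts.tp,
            "TN": self.counts.tn,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
            "SE": self.se,
            "SP": self.sp,
            "PR": self.pr,
            "F1": self.f1,
            "ACC": self.acc,
            "MCC": self.mcc,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        if self.aupr is not None:
            d["AUPR"] = self.aupr
        return d


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> EvaluationResult:
    """All threshold metrics from one confusion matrix."""
    if counts.total == 0:
        raise ValueError("no samples evaluated")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: list[str] = []
    se = _ratio(tp, tp + fn, "SE", undefined)
    sp = _ratio(tn, tn + fp, "SP", undefined)
    pr = _ratio(tp, tp + fp, "PR", undefined)
    f1 = _ratio(2 * se * pr, se + pr, "F1", undefined)
    acc = (tp + tn) / counts.total
    mcc_den = math.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "MCC", undefined)
    if undefined:
        _warnings.warn(
            f"metrics with zero denominator reported as 0: {', '.join(undefined)}",
            stacklevel=2,
        )
    return EvaluationResult(
        counts=counts, se=se, sp=sp, pr=pr, f1=f1, acc=acc, mcc=mcc,
        undefined_metrics=tuple(undefined),
    )


def counts_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve as (FPR, TPR) points plus trapezoid AUC (ties by midrank)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


def pr_auc(scores, labels) -> tuple[np.ndarray, float]:
    """Precision-recall curve points plus step-integral area (AUPR)."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0:
        raise ValueError("AUPR needs at least one positive sample")
    precision, recall, _ = precision_recall_curve(labels, np.asarray(scores, dtype=float))
    area = float(average_precision_score(labels, np.asarray(scores, dtype=float)))
    return np.column_stack([recall, precision]), area


def _evaluate_splits(X, y, splits, estimator) -> EvaluationResult:
    """Fit/score the estimator per split; aggregate counts and pool scores."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    all_scores = np.empty(len(y), dtype=float)
    all_pred = np.empty(len(y), dtype=int)
    per_fold: list[EvaluationResult] = []
    for train_idx, test_idx in splits:
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                "a training split contains a single class; dataset too small "
                "or too imbalanced for this protocol"
            )
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        all_pred[test_idx] = est.predict(X[test_idx])
        all_scores[test_idx] = est.decision_function(X[test_idx])
        if len(test_idx) > 1:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                per_fold.append(
                    compute_metrics(counts_from_predictions(y[test_idx], all_pred[test_idx]))
                )
    result = compute_metrics(counts_from_predictions(y, all_pred))
    _, result.auc = roc_auc(all_scores, y)
    _, result.aupr = pr_auc(all_scores, y)
    result.per_fold = per_fold
    return result


def jackknife(X, y, estimator: HairpinClassifier | None = None) -> EvaluationResult:
    """Leave-one-out evaluation: n rounds, each holding out one sample.

    Confusion counts are aggregated over rounds; ROC/PR are computed from
    the pooled held-out decision scores. Normalisation is refitted on the
    n-1 training rows of every round.
    """
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 3:
        raise ValueError("jackknife needs at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("jackknife needs both classes present")
    estimator = estimator if estimator is not None else HairpinClassifier()
    splits = [
        (np.concatenate([np.arange(i), np.arange(i + 1, n)]), np.array([i]))
        for i in range(n)
    ]
    return _evaluate_splits(X, y, splits, estimator)


def kfold(
    X, y, k: int = 5, seed: int = 0, estimator: HairpinClassifier | None = None
) -> EvaluationResult:
    """Stratified k-fold evaluation; folds derived deterministically from
    ``seed``, sizes differing by at most one."""
    y = np.asarray(y).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError(f"k={k} exceeds the number of samples ({len(y)})")
    estimator = estimator if estimator is not None else HairpinClassifier()
    if k == len(y):  # boundary case: k = n is exactly the jackknife
        return jackknife(X, y, estimator=estimator)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return _evaluate_splits(X, y, list(cv.split(X, y)), estimator)


# ---------------------------------------------------------------------------
# information gain


@dataclass(frozen=True)
class IgScore:
    feature: str
    ig: float
    rank: int


def _entropy_bits(labels: np.ndarray) -> float:
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(
    X,
    y,
    feature_names: Sequence[str] | None = None,
    n_bins: int = 10,
    strategy: str = "uniform",
    normalize: bool = False,
) -> list[IgScore]:
    """Rank features by information gain about the class label.

    Each feature is discretised into ``n_bins`` bins (equal-width by default,
    ``strategy='quantile'`` for equal-frequency) and
    IG = H(y) - sum_b (n_b/n) H(y | bin b), in bits. With ``normalize=True``
    scores are divided by the maximum so the top feature prints 1.0.

    Returns scores sorted by descending IG; ranks are 1..n_features, ties
    broken by feature order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("information gain needs a non-constant label")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    h_y = _entropy_bits(y)
    igs = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if strategy == "quantile":
            edges = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)))
        elif strategy == "uniform":
            edges = np.linspace(col.min(), col.max(), n_bins + 1)
        else:
            raise ValueError(f"unknown binning strategy {strategy!r}")
        # interior edges only; digitize assigns the two outer bins correctly
        bins = np.digitize(col, edges[1:-1]) if len(edges) > 2 else np.zeros(len(col), int)
        cond = 0.0
        for b in np.unique(bins):
            mask = bins == b
            cond += mask.mean() * _entropy_bits(y[mask])
        igs[j] = h_y - cond
    if normalize and igs.max() > 0:
        igs = igs / igs.max()
    order = np.argsort(-igs, kind="stable")
    return [
        IgScore(feature=names[j], ig=float(igs[j]), rank=r + 1)
        for r, j in enumerate(order)
    ]


# ---------------------------------------------------------------------------
# ablation harness


def _subset_columns(subset: Sequence[str]) -> np.ndarray:
    cols: list[int] = []
    for block in subset:
        sl = FEATURE_BLOCKS.get(block.upper())
        if sl is None:
            raise ValueError(
                f"unknown feature block {block!r}; available: {sorted(FEATURE_BLOCKS)}"
            )
        cols.extend(range(sl.start, sl.stop))
    if not cols:
        raise ValueError("empty feature subset")
    return np.asarray(sorted(set(cols)), dtype=int)


def ablation_harness(
    X,
    y,
    subsets: Sequence[Sequence[str]] = (
        ("PSFMI",), ("SSFMI",), ("PSFMI", "MFE"), ("SSFMI", "MFE"), ("PSFMI", "SSFMI", "MFE"),
    ),
    protocol: str = "jackknife",
    k: int = 5,
    seed: int = 0,
    estimator: HairpinClassifier | None = None,
    kernels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Evaluate feature-block subsets (and optionally kernels) on one dataset.

    ``X`` must be in the canonical 55-column layout. Returns one row per
    subset (x kernel) with SE/SP/PR/F1/ACC/MCC/AUC/AUPR columns.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"ablation requires the canonical {len(FEATURE_NAMES)}-column layout"
        )
    estimator = estimator if estimator is not None else HairpinClassifier()
    kernels = list(kernels) if kernels is not None else [estimator.kernel]
    rows = []
    for kernel in kernels:
        for subset in subsets:
            cols = _subset_columns(subset)
            est = clone(estimator).set_params(kernel=kernel)
            if protocol == "jackknife":
                res = jackknife(X[:, cols], y, estimator=est)
            elif protocol == "kfold":
                res = kfold(X[:, cols], y, k=k, seed=seed, estimator=est)
            else:
                raise ValueError(f"unknown protocol {protocol!r}")
            row = {"features": "+".join(s.upper() for s in subset), "kernel": kernel,
                   "n_features": len(cols)}
            row.update(res.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
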