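"""Linear-SVM stress/rest classification under leave-one-subject-out CV.

Every fold holds out *all* records of one subject, so performance
estimates transfer to unseen people.  Inside each training fold the
features are Relief-F-ranked (unless a precomputed global ranking is
supplied), z-scored with training-fold statistics, and fed to a linear
support vector machine; the held-out subject's records are then scored.
Confusion counts aggregate over folds, with stress as the positive
class.

``sweep_feature_counts`` repeats the cross-validation for every
feature-count 1..26 along the ranked order and reports the best count;
``segment_sweep`` repeats the whole procedure over the 3x3 grid of
ultra-short windows (first/middle/last x 1/2/3 min) plus the 5-min
baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .errors import DataError, ParameterError
from .features import FEATURE_NAMES
from .records import Cohort, REST, STRESS
from .relief import _relieff
from .segmentation import DURATIONS_S, POSITIONS, SegmentSpec, build_ultra_short_dataset

__all__ = [
    "SVMConfig",
    "ConfusionCounts",
    "Metrics",
    "metrics",
    "f1_from_precision_recall",
    "StressClassifier",
    "losocv",
    "sweep_feature_counts",
    "segment_sweep",
    "CVReport",
]


@dataclass(frozen=True)
class SVMConfig:
    """Linear SVM settings: regularization C and per-fold z-scoring."""

    C: float = 1.0
    standardize: bool = True
    relief_k: int = 10

    def __post_init__(self):
        if self.C <= 0:
            raise ParameterError("C must be positive")


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive=STRESS):
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t, pos_p = y_true == positive, y_pred == positive
        return cls(
            tp=int(np.count_nonzero(pos_t & pos_p)),
            tn=int(np.count_nonzero(~pos_t & ~pos_p)),
            fp=int(np.count_nonzero(~pos_t & pos_p)),
            fn=int(np.count_nonzero(pos_t & ~pos_p)),
        )


@dataclass
class Metrics:
    """Accuracy/precision/recall/F1 in percent; NaN marks a zero-denominator
    sentinel (never silently 0)."""

    accuracy: float
    precision: float
    recall: float
    f1: float


def metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall and F1 (all %) from confusion counts."""
    if counts.total == 0:
        raise DataError("metrics undefined for all-zero confusion counts")
    accuracy = 100.0 * (counts.tp + counts.tn) / counts.total
    precision = (100.0 * counts.tp / (counts.tp + counts.fp)
                 if counts.tp + counts.fp > 0 else math.nan)
    recall = (100.0 * counts.tp / (counts.tp + counts.fn)
              if counts.tp + counts.fn > 0 else math.nan)
    f1 = f1_from_precision_recall(precision, recall)
    return Metrics(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def f1_from_precision_recall(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if math.isnan(precision_pct) or math.isnan(recall_pct):
        return math.nan
    if precision_pct + recall_pct == 0:
        return math.nan
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


class StressClassifier(ClassifierMixin, BaseEstimator):
    """Relief-F-ranked, z-scored linear SVM (scikit-learn API).

    Parameters
    ----------
    n_features : int or None
        Top-ranked features to keep; None keeps all.
    C : float
        SVM regularization.
    standardize : bool
        z-score features with training statistics.
    relief_k : int
        Relief-F neighbour count.
    feature_order : array of column indices or None
        Precomputed ranking (best first).  When given, Relief-F is not
        re-run at fit time — the "global ranking" mode.
    """

    def __init__(self, n_features=None, C: float = 1.0, standardize: bool = True,
                 relief_k: int = 10, feature_order=None):
        self.n_features = n_features
        self.C = C
        self.standardize = standardize
        self.relief_k = relief_k
        self.feature_order = feature_order

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.feature_order is not None:
            order = np.asarray(self.feature_order, dtype=int)
        else:
            weights = _relieff(X, y, self.relief_k)
            order = np.lexsort((np.arange(X.shape[1]), -weights))
        n = X.shape[1] if self.n_features is None else int(self.n_features)
        if not 1 <= n <= X.shape[1]:
            raise ParameterError(f"n_features must lie in 1..{X.shape[1]}")
        self.order_ = order
        self.support_ = order[:n]
        Xs = X[:, self.support_]
        if self.standardize:
            self.scaler_ = StandardScaler().fit(Xs)
            Xs = self.scaler_.transform(Xs)
        else:
            self.scaler_ = None
        self.svc_ = SVC(kernel="linear", C=self.C).fit(Xs, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        X = check_array(X, dtype=float)
        Xs = X[:, self.support_]
        if self.scaler_ is not None:
            Xs = self.scaler_.transform(Xs)
        return self.svc_.predict(Xs)


@dataclass
class FoldOutcome:
    n_features: int
    counts: ConfusionCounts
    metrics: Metrics
    predictions: pd.DataFrame  # subject_id, condition, predicted


@dataclass
class CVReport:
    """Feature-count sweep outcome: one LOSOCV result per count."""

    by_count: dict  # n_features -> FoldOutcome
    best_n_features: int

    @property
    def best(self) -> FoldOutcome:
        return self.by_count[self.best_n_features]

    def curve(self) -> pd.DataFrame:
        rows = [
            {"n_features": n, "accuracy": o.metrics.accuracy,
             "precision": o.metrics.precision, "recall": o.metrics.recall,
             "f1": o.metrics.f1}
            for n, o in sorted(self.by_count.items())
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "best_n_features": self.best_n_features,
            "curve": self.curve().to_dict(orient="records"),
            "best": {
                "counts": vars(self.best.counts),
                "metrics": vars(self.best.metrics),
            },
        }


def _split_table(table: pd.DataFrame, feature_names):
    missing = [c for c in ("subject_id", "condition", *feature_names)
               if c not in table.columns]
    if missing:
        raise DataError(f"feature table is missing columns: {missing}")
    X = table[list(feature_names)].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise DataError("feature table contains non-finite values "
                        "(undefined-entropy sentinels must be excluded first)")
    y = table["condition"].to_numpy()
    groups = table["subject_id"].to_numpy()
    return X, y, groups


def _fold_rankings(X, y, groups, mode: str, k: int):
    """Ranked column orders: one per held-out subject (per_fold) or a
    single shared order (global)."""
    if mode == "global":
        weights = _relieff(X, y, k)
        order = np.lexsort((np.arange(X.shape[1]), -weights))
        return {subject: order for subject in np.unique(groups)}
    if mode != "per_fold":
        raise ParameterError("ranking_mode must be 'per_fold' or 'global'")
    orders = {}
    for subject in np.unique(groups):
        train = groups != subject
        weights = _relieff(X[train], y[train], k)
        orders[subject] = np.lexsort((np.arange(X.shape[1]), -weights))
    return orders


def losocv(table: pd.DataFrame, ranking_mode: str = "per_fold",
           svm: SVMConfig = SVMConfig(), n_features=None,
           feature_names=FEATURE_NAMES, _rankings=None) -> FoldOutcome:
    """Leave-one-subject-out cross-validation at a fixed feature count."""
    X, y, groups = _split_table(table, feature_names)
    subjects = np.unique(groups)
    if subjects.size < 2:
        raise DataError("LOSOCV needs at least two subjects")
    for subject in subjects:
        if np.unique(y[groups != subject]).size < 2:
            raise DataError(
                f"training fold without subject {subject} has a single class"
            )
    rankings = _rankings or _fold_rankings(X, y, groups, ranking_mode, svm.relief_k)
    frames = []
    y_true_all, y_pred_all = [], []
    for subject in subjects:
        test = groups == subject
        clf = StressClassifier(
            n_features=n_features, C=svm.C, standardize=svm.standardize,
            relief_k=svm.relief_k, feature_order=rankings[subject],
        ).fit(X[~test], y[~test])
        pred = clf.predict(X[test])
        y_true_all.append(y[test])
        y_pred_all.append(pred)
        frames.append(pd.DataFrame({
            "subject_id": groups[test],
            "condition": y[test],
            "predicted": pred,
        }))
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    counts = ConfusionCounts.from_predictions(y_true, y_pred, positive=STRESS)
    n = len(feature_names) if n_features is None else int(n_features)
    return FoldOutcome(
        n_features=n,
        counts=counts,
        metrics=metrics(counts),
        predictions=pd.concat(frames, ignore_index=True),
    )


def sweep_feature_counts(table: pd.DataFrame, svm: SVMConfig = SVMConfig(),
                         ranking_mode: str = "per_fold",
                         feature_names=FEATURE_NAMES) -> CVReport:
    """LOSOCV at every feature count 1..len(features); best = argmax
    accuracy with ties going to the smaller count."""
    X, y, groups = _split_table(table, feature_names)
    rankings = _fold_rankings(X, y, groups, ranking_mode, svm.relief_k)
    by_count = {}
    for n in range(1, len(feature_names) + 1):
        by_count[n] = losocv(table, ranking_mode, svm, n_features=n,
                             feature_names=feature_names, _rankings=rankings)
    best = max(sorted(by_count), key=lambda n: (by_count[n].metrics.accuracy, -n))
    return CVReport(by_count=by_count, best_n_features=best)


def segment_sweep(cohort: Cohort, svm: SVMConfig = SVMConfig(),
                  ranking_mode: str = "per_fold",
                  extract=None, durations=DURATIONS_S) -> pd.DataFrame:
    """Best LOSOCV accuracy/F1 over the position x duration grid plus the
    full-length baseline.

    ``extract`` maps a cohort to a feature table; defaults to the
    standard pipeline extractor.  Outlier screening runs once on the
    full records; segments are not re-screened.
    """
    if extract is None:
        from .pipeline import clean_cohort, extract_feature_table

        cohort = clean_cohort(cohort)
        extract = lambda c: extract_feature_table(c, screen=False)  # noqa: E731
    rows = []
    for duration in durations:
        for position in POSITIONS:
            spec = SegmentSpec(position=position, duration_s=duration)
            segments = build_ultra_short_dataset(cohort, spec)
            report = sweep_feature_counts(extract(segments), svm, ranking_mode)
            rows.append({
                "position": position, "duration_s": duration,
                "best_n_features": report.best_n_features,
                "accuracy": report.best.metrics.accuracy,
                "f1": report.best.metrics.f1,
            })
    baseline = sweep_feature_counts(extract(cohort), svm, ranking_mode)
    rows.append({
        "position": "full", "duration_s": float("nan"),
        "best_n_features": baseline.best_n_features,
        "accuracy": baseline.best.metrics.accuracy,
        "f1": baseline.best.metrics.f1,
    })
    return pd.DataFrame(rows)
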