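"""Relief-F feature weighting and ranking.

The deterministic two-class Relief-F variant: every sample is visited
(no subsampling); for each, the k nearest same-class neighbours (hits)
and k nearest other-class neighbours (misses) are found by Manhattan
distance on min-max-scaled features, and each feature's weight
accumulates

    W[f] += sum(miss diffs)/(n*k) - sum(hit diffs)/(n*k)

so features that separate the classes (large between-class, small
within-class differences) get large positive weights.  Min-max scaling
inside the algorithm makes the ranking invariant to positive rescaling
of any feature column.

:class:`ReliefF` exposes the same computation as a scikit-learn feature
selector so it can sit in a Pipeline ahead of a classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .errors import DataError, ParameterError
from .features import FEATURE_NAMES

__all__ = ["ReliefWeights", "ReliefF", "relieff_weights", "rank_features"]


@dataclass
class ReliefWeights:
    weights: np.ndarray
    k: int
    feature_names: list
    order: list  # feature names in descending weight


def _relieff(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    n, n_features = X.shape
    classes = np.unique(y)
    if classes.size != 2:
        raise DataError("Relief-F here is two-class; got "
                        f"{classes.size} classes")
    for c in classes:
        if np.count_nonzero(y == c) <= k:
            raise ParameterError(
                f"k={k} must be smaller than the size of every class "
                f"(class {c!r} has {np.count_nonzero(y == c)} samples)"
            )
    # min-max scale; constant features contribute zero everywhere
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Z = (X - lo) / span
    weights = np.zeros(n_features)
    for i in range(n):
        diffs = np.abs(Z - Z[i])           # (n, n_features)
        dist = diffs.sum(axis=1)           # Manhattan
        dist[i] = np.inf                   # exclude self
        same = y == y[i]
        for is_hit in (True, False):
            mask = same if is_hit else ~same
            mask = mask.copy()
            mask[i] = False
            idx = np.flatnonzero(mask)
            nearest = idx[np.argsort(dist[idx], kind="stable")[:k]]
            contrib = diffs[nearest].sum(axis=0) / (n * k)
            weights += -contrib if is_hit else contrib
    return weights


def relieff_weights(X, y, k: int = 10, feature_names=None) -> ReliefWeights:
    """Relief-F weights for a two-class feature table.

    ``X`` may be a DataFrame (column names become feature names) or an
    array with ``feature_names`` supplied.
    """
    names = feature_names
    if hasattr(X, "columns"):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if names is None:
        names = [f"f{i}" for i in range(X.shape[1])]
    if np.any(~np.isfinite(X)):
        raise DataError("feature table contains missing/non-finite values")
    weights = _relieff(X, y, k)
    order = rank_features(weights, names)
    return ReliefWeights(weights=weights, k=k, feature_names=names, order=order)


def rank_features(weights, feature_names) -> list:
    """Feature names sorted by descending weight; ties broken by the
    canonical feature order, then lexicographically for unknown names."""
    canon = {name: i for i, name in enumerate(FEATURE_NAMES)}

    def tiekey(name):
        return (canon.get(name, len(FEATURE_NAMES)), name)

    paired = sorted(
        zip(weights, feature_names),
        key=lambda wn: (-wn[0],) + tiekey(wn[1]),
    )
    return [name for _, name in paired]


class ReliefF(SelectorMixin, BaseEstimator):
    """Relief-F feature selector (scikit-learn API).

    Parameters
    ----------
    n_features_to_select : int or None
        Keep the top-ranked features; None keeps all (ranking only).
    k : int
        Neighbour count per class (default 10).

    Attributes
    ----------
    weights_ : ndarray of shape (n_features,)
    ranking_ : ndarray of feature indices, best first
    """

    def __init__(self, n_features_to_select=None, k: int = 10):
        self.n_features_to_select = n_features_to_select
        self.k = k

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.n_features_in_ = X.shape[1]
        self.weights_ = _relieff(X, y, self.k)
        # argsort on (-weight, index): ties keep column order
        self.ranking_ = np.lexsort((np.arange(X.shape[1]), -self.weights_))
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        n = self.n_features_to_select
        if n is None:
            n = self.n_features_in_
        if not 1 <= n <= self.n_features_in_:
            raise ParameterError(
                f"n_features_to_select must lie in 1..{self.n_features_in_}"
            )
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:n]] = True
        return mask
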