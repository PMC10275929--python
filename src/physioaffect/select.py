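"""ReliefF feature weighting and the cross-participant median-positive rule.

ReliefF scores each feature by how well it separates nearest same-class
neighbours (hits) from nearest other-class neighbours (misses).  For each
sampled instance R_i the weight of attribute A is updated

    W[A] <- W[A] - sum_j diff(A, R_i, H_j) / (m k)
                 + sum_{C != class(R_i)} P(C)/(1 - P(class(R_i)))
                   * sum_j diff(A, R_i, M_j(C)) / (m k)

with diff(A, I1, I2) = |I1[A] - I2[A]| / (max(A) - min(A)), neighbours under
Manhattan distance on range-normalized features, and empirical class priors.
With range-normalized differences every weight lies in [-1, 1].

Here m = all instances (deterministic, no sampling noise), ties are broken by
lowest instance index, and zero-range features contribute nothing (weight 0).

Per-participant weights are aggregated across a cohort by the per-feature
median; features with strictly positive median form the global optimal set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data


class ReliefF(SelectorMixin, BaseEstimator):
    """ReliefF feature weighting as a scikit-learn selector.

    Parameters
    ----------
    n_neighbors : int, default=5
        k, the number of nearest hits and of nearest misses per class.
    n_samples : int or None, default=None
        m, the number of sampled instances; ``None`` uses every instance
        deterministically (in index order).
    threshold : float, default=0.0
        ``transform`` keeps features with weight strictly above this.

    Attributes
    ----------
    weights_ : ndarray of shape (n_features,)
        The ReliefF relevance weight of each feature, in [-1, 1].

    Notes
    -----
    Feature ranges for the diff normalization are computed on the data passed
    to ``fit`` only, so a held-out test split never influences the weights.
    """

    def __init__(self, n_neighbors: int = 5, n_samples: int | None = None,
                 threshold: float = 0.0):
        self.n_neighbors = n_neighbors
        self.n_samples = n_samples
        self.threshold = threshold

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=2)
        y = np.asarray(y)
        k = self.n_neighbors
        classes, y_idx = np.unique(y, return_inverse=True)
        counts = np.bincount(y_idx)
        if len(classes) < 2:
            raise ValueError("ReliefF needs at least 2 classes")
        for c, n_c in zip(classes, counts):
            if n_c <= k:
                raise ValueError(
                    f"class {c!r} has {n_c} instances; needs more than k={k}"
                )
        n, p = X.shape
        span = X.max(axis=0) - X.min(axis=0)
        informative = span > 0
        # range-normalize; constant features get diff 0 by zeroing the column
        Z = np.zeros_like(X, dtype=float)
        Z[:, informative] = X[:, informative] / span[informative]
        priors = counts / n

        if self.n_samples is None:
            sample_idx = np.arange(n)
        else:
            sample_idx = np.arange(min(self.n_samples, n))
        m = len(sample_idx)

        # Manhattan distances on normalized features; chunk to bound memory
        W = np.zeros(p)
        for start in range(0, m, 512):
            rows = sample_idx[start:start + 512]
            D = np.abs(Z[rows, None, :] - Z[None, :, :]).sum(axis=2)
            for local, i in enumerate(rows):
                d = D[local]
                d_sort = d.copy()
                d_sort[i] = np.inf  # never own neighbour
                for ci, c in enumerate(classes):
                    members = np.flatnonzero(y_idx == ci)
                    # stable argsort => ties broken by lowest instance index
                    order = members[np.argsort(d_sort[members], kind="stable")[:k]]
                    contrib = np.abs(Z[order] - Z[i]).sum(axis=0) / (m * k)
                    if ci == y_idx[i]:
                        W -= contrib
                    else:
                        W += priors[ci] / (1.0 - priors[y_idx[i]]) * contrib
        self.weights_ = W
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.weights_ > self.threshold

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


@dataclass
class ReliefFWeights:
    """Per-participant ReliefF weights for one value of k."""

    participant_id: str
    k: int
    weights: dict[str, float]


@dataclass
class OptimalFeatureSet:
    """Features with positive median weight across participants."""

    features: list[str]
    medians: dict[str, float] = field(default_factory=dict)


def relieff(
    X: pd.DataFrame | np.ndarray,
    y,
    k: int = 5,
    feature_names: list[str] | None = None,
    participant_id: str = "",
    m: int | None = None,
) -> ReliefFWeights:
    """Functional front-end over :class:`ReliefF` returning named weights."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    est = ReliefF(n_neighbors=k, n_samples=m).fit(X, y)
    return ReliefFWeights(
        participant_id=participant_id, k=k,
        weights=dict(zip(feature_names, est.weights_)),
    )


def weight_stability_report(
    X, y, k_values=(1, 3, 5, 10), participant_id: str = ""
) -> dict[int, ReliefFWeights]:
    """ReliefF weights for each k, for checking cross-k agreement of the
    positive-weight feature set."""
    return {k: relieff(X, y, k=k, participant_id=participant_id) for k in k_values}


def positive_features(w: ReliefFWeights) -> set[str]:
    return {f for f, v in w.weights.items() if v > 0}


def optimal_feature_set(per_participant: list[ReliefFWeights]) -> OptimalFeatureSet:
    """Median weight per feature across participants; keep medians > 0.

    Selected features are ordered by descending median weight.
    """
    if not per_participant:
        raise ValueError("need at least one participant's weights")
    keys = list(per_participant[0].weights)
    for w in per_participant[1:]:
        if set(w.weights) != set(keys):
            raise ValueError(
                f"inconsistent feature keys for participant {w.participant_id!r}"
            )
    mat = np.array([[w.weights[f] for f in keys] for w in per_participant])
    med = np.median(mat, axis=0)
    medians = dict(zip(keys, med.astype(float)))
    selected = sorted((f for f in keys if medians[f] > 0), key=lambda f: -medians[f])
    return OptimalFeatureSet(features=selected, medians=medians)
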