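"""Relief-F feature ranking.

Relief-F scores a feature by how well it separates nearby instances of
different classes while staying stable across nearby instances of the same
class. For each considered instance R it finds the nearest same-class hit H
and, for every other class C, the nearest miss M(C); the weight of feature
A is updated as

    W[A] <- W[A] - diff(A; R, H)/n
                 + sum_{C != class(R)} P(C) * diff(A; R, M(C)) / n

where n is the number of instances considered, P(C) the empirical class
frequency, and diff the absolute difference scaled by the feature's range
over the whole table (0 for a constant feature). Nearest neighbours use
Manhattan distance on the same range-scaled features, R itself excluded,
with ties broken toward the lowest row index.

Note the miss term above weights by the raw prior P(C). The variant that
additionally divides by 1 - P(class(R)) (so the miss weights sum to one) is
available via ``normalized_priors=True``.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .features import FEATURE_NAMES


class ReliefF(SelectorMixin, BaseEstimator):
    """Relief-F feature weighting and ranking.

    Parameters
    ----------
    n_samples : int or None
        Number of instances R to consider. None (default) iterates over
        every instance in order, which makes the result deterministic;
        an integer draws that many instances without replacement using
        ``random_state``.
    n_features_to_select : int or None
        Size of the subset kept by :meth:`transform`; None keeps all.
    normalized_priors : bool
        If True, weight each miss class by P(C)/(1 - P(class(R))) instead
        of the raw prior P(C).
    random_state : int or None
        Seed for the instance subsample (ignored when ``n_samples`` is
        None).

    Attributes
    ----------
    weights_ : ndarray of shape (n_features,)
        Relevance weight W[A] per feature.
    ranking_ : ndarray of shape (n_features,)
        Feature indices sorted by descending weight, ties broken by the
        smaller index.
    priors_ : dict
        Empirical class probabilities P(C) used in the update.
    """

    def __init__(
        self,
        n_samples: int | None = None,
        n_features_to_select: int | None = None,
        normalized_priors: bool = False,
        random_state: int | None = None,
    ):
        self.n_samples = n_samples
        self.n_features_to_select = n_features_to_select
        self.normalized_priors = normalized_priors
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=2)
        n_rows, d = X.shape
        classes, y_idx, counts = np.unique(
            np.asarray(y, dtype=object), return_inverse=True, return_counts=True
        )
        if len(classes) < 2:
            raise ValueError("Relief-F needs at least 2 classes")
        if counts.min() < 2:
            bad = classes[counts.argmin()]
            raise ValueError(
                f"class {bad!r} has a single instance; no same-class hit exists"
            )
        span = X.max(axis=0) - X.min(axis=0)
        # constant features: every scaled difference is exactly 0
        denom = np.where(span > 0, span, 1.0)
        Z = (X - X.min(axis=0)) / denom

        priors = counts / n_rows
        if self.n_samples is None:
            sample_idx = np.arange(n_rows)
        else:
            if not isinstance(self.n_samples, numbers.Integral) or self.n_samples < 1:
                raise ValueError("n_samples must be a positive integer or None")
            if self.n_samples > n_rows:
                raise ValueError(
                    f"n_samples={self.n_samples} exceeds the {n_rows} instances"
                )
            rng = np.random.default_rng(self.random_state)
            sample_idx = rng.choice(n_rows, size=int(self.n_samples), replace=False)
        n = len(sample_idx)

        members = [np.flatnonzero(y_idx == c) for c in range(len(classes))]
        W = np.zeros(d)
        for r in sample_idx:
            diffs = np.abs(Z - Z[r])  # (n_rows, d), range-scaled
            dist = diffs.sum(axis=1)
            dist[r] = np.inf  # R never its own neighbour
            c_r = y_idx[r]
            for c, rows in enumerate(members):
                nearest = rows[np.argmin(dist[rows])]  # first min = lowest index
                if c == c_r:
                    W -= diffs[nearest] / n
                else:
                    p = priors[c]
                    if self.normalized_priors:
                        p = p / (1.0 - priors[c_r])
                    W += p * diffs[nearest] / n

        self.n_features_in_ = d
        self.classes_ = classes
        self.priors_ = dict(zip(classes, priors))
        self.weights_ = W
        self.ranking_ = np.lexsort((np.arange(d), -W))
        self.n_sampled_ = n
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "weights_")
        k = self.n_features_to_select
        if k is None:
            k = self.n_features_in_
        if not 1 <= k <= self.n_features_in_:
            raise ValueError(
                f"n_features_to_select must be in [1, {self.n_features_in_}]"
            )
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:k]] = True
        return mask

    def top_features(self, k: int) -> np.ndarray:
        """Indices of the k best-ranked features (ranking order preserved)."""
        check_is_fitted(self, "ranking_")
        if not 1 <= k <= self.n_features_in_:
            raise ValueError(f"k must be in [1, {self.n_features_in_}]")
        return self.ranking_[:k].copy()


@dataclass(frozen=True)
class ReliefFResult:
    """Weights and ranking of a fitted Relief-F run, keyed by feature name."""

    weights: dict[str, float]
    ranking: list[str]
    n: int
    params: dict

    def top(self, k: int) -> list[str]:
        if not 1 <= k <= len(self.ranking):
            raise ValueError(f"k must be in [1, {len(self.ranking)}]")
        return self.ranking[:k]


def relieff_weights(
    table: pd.DataFrame,
    n: int | None = None,
    seed: int | None = None,
    normalized_priors: bool = False,
) -> ReliefFResult:
    """Run Relief-F on a feature table (columns ``label`` + F1..F19)."""
    names = [c for c in table.columns if c in FEATURE_NAMES]
    if not names:
        raise ValueError("table has no feature columns F1..F19")
    est = ReliefF(
        n_samples=n, random_state=seed, normalized_priors=normalized_priors
    ).fit(table[names].to_numpy(float), table["label"].to_numpy())
    return ReliefFResult(
        weights={nm: float(w) for nm, w in zip(names, est.weights_)},
        ranking=[names[i] for i in est.ranking_],
        n=est.n_sampled_,
        params={
            "metric": "manhattan",
            "n_samples": n,
            "seed": seed,
            "normalized_priors": normalized_priors,
            "priors": {str(k): float(v) for k, v in est.priors_.items()},
        },
    )


def rank_features(result: ReliefFResult) -> list[str]:
    """Feature names in descending-weight order (precomputed in result)."""
    return list(result.ranking)
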