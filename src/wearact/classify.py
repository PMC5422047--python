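"""Native Gaussian naive Bayes and k-nearest-neighbour classifiers, plus a
plugin registry for external algorithms.

The two native models cover the headline settings of this kind of activity
analysis (NB and kNN with k=1,3 dominate the best-model tables); heavier
algorithms (polynomial-kernel SVM, multilayer perceptron, decision trees,
Bayesian networks, rule learners) enter through the plugin registry, which
wraps any estimator honouring the sklearn fit/predict contract.

Determinism conventions: class ordering follows the activity schema order
passed at fit time (falling back to sorted unique labels); all argmax ties
— NB posteriors, kNN votes — resolve to the earliest class in that order,
and kNN distance ties resolve to the lowest training-row index.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import FEATURE_NAMES
from .recording import ACTIVITIES


def _ordered_classes(y: np.ndarray, class_order) -> np.ndarray:
    present = set(map(str, y))
    if class_order is None:
        class_order = list(ACTIVITIES) if present <= set(ACTIVITIES) else sorted(present)
    ordered = [c for c in class_order if c in present]
    missing = present - set(ordered)
    if missing:
        raise ValueError(f"labels {sorted(missing)} not in the class order")
    return np.asarray(ordered, dtype=object)


class NaiveBayesClassifier(ClassifierMixin, BaseEstimator):
    """Gaussian naive Bayes.

    Each feature is modelled per class as an independent Gaussian; priors
    are class frequencies. Posteriors are evaluated in log space and
    normalised to sum to one. ``var_floor`` guards against zero-variance
    features.

    Attributes (after fit): ``classes_``, ``priors_``, ``theta_`` (class x
    feature means), ``var_`` (class x feature variances, floored).
    """

    def __init__(self, var_floor: float = 1e-9, class_order=None):
        self.var_floor = var_floor
        self.class_order = class_order

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=object), dtype=float)
        self.classes_ = _ordered_classes(y, self.class_order)
        k, d = len(self.classes_), X.shape[1]
        self.priors_ = np.empty(k)
        self.theta_ = np.empty((k, d))
        self.var_ = np.empty((k, d))
        for i, c in enumerate(self.classes_):
            rows = X[y == c]
            if rows.shape[0] < 2:
                raise ValueError(
                    f"class {c!r} has {rows.shape[0]} training row(s); "
                    "at least 2 are needed to estimate a variance"
                )
            self.priors_[i] = rows.shape[0] / X.shape[0]
            self.theta_[i] = rows.mean(axis=0)
            self.var_[i] = np.maximum(rows.var(axis=0), self.var_floor)
        self.n_features_in_ = d
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        check_is_fitted(self, "theta_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        ll = np.empty((X.shape[0], len(self.classes_)))
        for i in range(len(self.classes_)):
            log_gauss = -0.5 * (
                np.log(2.0 * np.pi * self.var_[i])
                + (X - self.theta_[i]) ** 2 / self.var_[i]
            ).sum(axis=1)
            ll[:, i] = np.log(self.priors_[i]) + log_gauss
        return ll

    def predict_log_proba(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        return jll - logsumexp(jll, axis=1, keepdims=True)

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        return self.classes_[np.argmax(jll, axis=1)]


class KNNClassifier(ClassifierMixin, BaseEstimator):
    """k-nearest-neighbour majority vote.

    Distances are Euclidean on per-feature min-max scaling fitted on the
    training data (a constant feature scales to zero spread and is inert).
    Vote ties resolve to the earliest class in the schema order; distance
    ties to the lowest training-row index.
    """

    def __init__(self, n_neighbors: int = 1, class_order=None):
        self.n_neighbors = n_neighbors
        self.class_order = class_order

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=object), dtype=float)
        if not 1 <= self.n_neighbors <= X.shape[0]:
            raise ValueError(
                f"n_neighbors={self.n_neighbors} invalid for {X.shape[0]} rows"
            )
        self.classes_ = _ordered_classes(y, self.class_order)
        self.min_ = X.min(axis=0)
        span = X.max(axis=0) - self.min_
        self.scale_ = np.where(span > 0, span, 1.0)
        self._Z = (X - self.min_) / self.scale_
        class_pos = {c: i for i, c in enumerate(self.classes_)}
        self._y_idx = np.fromiter((class_pos[c] for c in y), dtype=int, count=len(y))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "scale_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Z = (X - self.min_) / self.scale_
        out = np.empty(X.shape[0], dtype=object)
        for i, z in enumerate(Z):
            d2 = ((self._Z - z) ** 2).sum(axis=1)
            order = np.argsort(d2, kind="stable")[: self.n_neighbors]
            votes = np.bincount(self._y_idx[order], minlength=len(self.classes_))
            out[i] = self.classes_[int(np.argmax(votes))]
        return out


# --------------------------------------------------------------------------
# algorithm registry

_NATIVE: dict[str, Callable[[], BaseEstimator]] = {
    "NB": NaiveBayesClassifier,
    "1NN": lambda: KNNClassifier(n_neighbors=1),
    "3NN": lambda: KNNClassifier(n_neighbors=3),
}

_PLUGINS: dict[str, Callable[[], BaseEstimator]] = {}


def register_classifier(name: str, factory: Callable[[], BaseEstimator]) -> None:
    """Register an external classifier factory under ``name``."""
    if name in _NATIVE:
        raise ValueError(f"{name!r} is a native algorithm and cannot be replaced")
    _PLUGINS[name] = factory


def available_algorithms() -> list[str]:
    return list(_NATIVE) + sorted(_PLUGINS)


def make_classifier(tag: str) -> BaseEstimator:
    """Instantiate a classifier by tag (native NB/1NN/3NN or a plugin)."""
    name = tag.removeprefix("plugin:")
    if name in _NATIVE:
        return _NATIVE[name]()
    if name in _PLUGINS:
        return _PLUGINS[name]()
    raise KeyError(
        f"unknown algorithm {tag!r}; available: {', '.join(available_algorithms())}"
    )


def register_sklearn_plugins(random_state: int = 0) -> None:
    """Register reference adapters for the heavier algorithm families.

    SVM: polynomial-kernel SVC; NN: multilayer perceptron; J48-style
    pruned decision tree. Each is wrapped in a min-max scaling pipeline
    where scale matters and seeded for reproducibility.
    """
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import MinMaxScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    register_classifier(
        "SVM",
        lambda: make_pipeline(MinMaxScaler(), SVC(kernel="poly", degree=1, C=1.0)),
    )
    register_classifier(
        "NN",
        lambda: make_pipeline(
            MinMaxScaler(),
            MLPClassifier(
                hidden_layer_sizes=(20,), max_iter=2000, random_state=random_state
            ),
        ),
    )
    register_classifier(
        "J48", lambda: DecisionTreeClassifier(random_state=random_state)
    )


# --------------------------------------------------------------------------
# thin table-level wrappers

def _subset_matrix(table: pd.DataFrame, subset: list[str]) -> np.ndarray:
    missing = [f for f in subset if f not in table.columns]
    if missing:
        raise ValueError(f"features {missing} missing from the table")
    if not subset:
        raise ValueError("feature subset is empty")
    bad = [f for f in subset if f not in FEATURE_NAMES]
    if bad:
        raise ValueError(f"unknown feature ids {bad}")
    return table[list(subset)].to_numpy(float)


class TrainedClassifier:
    """A fitted estimator bound to its algorithm tag and feature subset."""

    def __init__(self, algorithm: str, features: list[str], estimator: BaseEstimator):
        self.algorithm = algorithm
        self.features = list(features)
        self.estimator = estimator

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(_subset_matrix(table, self.features))


def train(algorithm: str, table: pd.DataFrame, subset: list[str]) -> TrainedClassifier:
    """Fit an algorithm (by tag) on the table restricted to ``subset``."""
    est = make_classifier(algorithm)
    est.fit(_subset_matrix(table, subset), table["label"].to_numpy(object))
    return TrainedClassifier(algorithm, subset, est)


def train_nb(table: pd.DataFrame, subset: list[str]) -> TrainedClassifier:
    return train("NB", table, subset)


def train_knn(table: pd.DataFrame, subset: list[str], k: int) -> TrainedClassifier:
    est = KNNClassifier(n_neighbors=k)
    est.fit(_subset_matrix(table, subset), table["label"].to_numpy(object))
    return TrainedClassifier(f"{k}NN", subset, est)


def predict(model: TrainedClassifier, row: pd.Series | pd.DataFrame):
    """Predict one feature row; returns (label, class-score dict).

    NB scores are normalised posteriors; estimators without predict_proba
    report an indicator score (1 for the predicted class).
    """
    frame = row.to_frame().T if isinstance(row, pd.Series) else row
    X = _subset_matrix(frame, model.features)
    est = model.estimator
    label = est.predict(X)[0]
    if hasattr(est, "predict_proba"):
        probs = est.predict_proba(X)[0]
        scores = {str(c): float(p) for c, p in zip(est.classes_, probs)}
    else:
        scores = {str(c): float(c == label) for c in est.classes_}
    return str(label), scores
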