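"""Independent brute-force oracles used to validate the implementation.

These are deliberately written in the most direct way possible (plain
loops, textbook formulas, sorting instead of selection) and share no code
with the package.
"""

from __future__ import annotations

import math

import numpy as np


def feature_vector_direct(samples: np.ndarray) -> list[float]:
    """The 19 windowed features evaluated term by term from their formulas."""
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    axes = [samples[:, k].tolist() for k in range(3)]
    means = [sum(ax) / n for ax in axes]
    sds = [
        math.sqrt(sum((v - mu) ** 2 for v in ax) / n)
        for ax, mu in zip(axes, means)
    ]
    maxs = [max(ax) for ax in axes]
    mins = [min(ax) for ax in axes]
    ranges = [mx - mn for mx, mn in zip(maxs, mins)]
    sd_mag = math.sqrt(sum(s**2 for s in sds))
    corrs = []
    for a, b in ((0, 1), (0, 2), (1, 2)):
        cov = sum(
            (x - means[a]) * (y - means[b]) for x, y in zip(axes[a], axes[b])
        ) / n
        denom = sds[a] * sds[b]
        corrs.append(cov / denom if denom > 0 else 0.0)
    return means + sds + maxs + mins + ranges + [sd_mag] + corrs


def relieff_direct(X: np.ndarray, y, normalized_priors: bool = False) -> np.ndarray:
    """O(n^2 d) evaluation of the Relief-F update over every instance.

    For each R: nearest same-class hit and one nearest miss per other
    class, by Manhattan distance on range-scaled features (ties to the
    lowest row index); weight update
    -diff(R,H)/n + sum_C P(C) diff(R,M(C))/n.
    """
    X = np.asarray(X, dtype=float)
    y = list(map(str, y))
    n_rows, d = X.shape
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    scaled = np.array(
        [[(X[i, a] - lo[a]) / span[a] if span[a] > 0 else 0.0 for a in range(d)]
         for i in range(n_rows)]
    )
    classes = sorted(set(y))
    prior = {c: y.count(c) / n_rows for c in classes}
    W = np.zeros(d)
    for r in range(n_rows):
        dists = []
        for j in range(n_rows):
            if j == r:
                dists.append(float("inf"))
            else:
                dists.append(sum(abs(scaled[r, a] - scaled[j, a]) for a in range(d)))
        nearest = {}
        for c in classes:
            best, best_d = None, float("inf")
            for j in range(n_rows):
                if y[j] == c and dists[j] < best_d:
                    best, best_d = j, dists[j]
            nearest[c] = best
        h = nearest[y[r]]
        for a in range(d):
            W[a] -= abs(scaled[r, a] - scaled[h, a]) / n_rows
        for c in classes:
            if c == y[r]:
                continue
            m = nearest[c]
            p = prior[c]
            if normalized_priors:
                p = p / (1.0 - prior[y[r]])
            for a in range(d):
                W[a] += p * abs(scaled[r, a] - scaled[m, a]) / n_rows
    return W


def knn_predict_direct(train_X, train_y, query, k: int, class_order) -> str:
    """Exhaustive-sort kNN with min-max scaling fitted on the training set."""
    train_X = np.asarray(train_X, dtype=float)
    lo, hi = train_X.min(axis=0), train_X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Z = (train_X - lo) / span
    q = (np.asarray(query, dtype=float) - lo) / span
    ranked = sorted(range(len(Z)), key=lambda j: (float(((Z[j] - q) ** 2).sum()), j))
    votes = [train_y[j] for j in ranked[:k]]
    counts = {c: votes.count(c) for c in class_order}
    return max(class_order, key=lambda c: (counts[c], -class_order.index(c)))


def sorted_median(values) -> float:
    """Median by explicit sort (odd: middle; even: mean of middle pair)."""
    vals = sorted(float(v) for v in values)
    n = len(vals)
    mid = n // 2
    return vals[mid] if n % 2 else 0.5 * (vals[mid - 1] + vals[mid])
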