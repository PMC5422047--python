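"""Subject-held-out cross-validation, the algorithm x feature-count sweep,
and accuracy aggregation.

Fold assignment happens at the subject level: a wearer contributes windows
either to training or to testing of a fold, never both, so reported
accuracies reflect generalisation to unseen people. With 12 subjects and 6
folds each test fold holds exactly 2 subjects.

Accuracy is macro-averaged: the unweighted mean of per-class accuracies
(per-class recall, confusion diagonal over row sum), which is insensitive
to class imbalance in the test windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import _subset_matrix, make_classifier
from .features import FEATURE_NAMES
from .recording import ACTIVITIES


@dataclass(frozen=True)
class FoldPlan:
    """Subject-level partition: one (train_ids, test_ids) pair per fold."""

    folds: list[tuple[list[str], list[str]]]
    seed: int | None = None

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_subject_folds(
    subject_ids, n_folds: int, seed: int | None = 0
) -> FoldPlan:
    """Shuffle subjects by seed and split into near-equal test folds."""
    ids = list(dict.fromkeys(map(str, subject_ids)))  # unique, order-stable
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if n_folds > len(ids):
        raise ValueError(f"cannot make {n_folds} folds from {len(ids)} subjects")
    perm = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    test_sets = [list(chunk) for chunk in np.array_split(shuffled, n_folds)]
    folds = [
        (sorted(set(ids) - set(test)), sorted(test)) for test in test_sets
    ]
    return FoldPlan(folds=folds, seed=seed)


def _class_order(labels) -> list[str]:
    present = list(dict.fromkeys(map(str, labels)))
    known = [a for a in ACTIVITIES if a in present]
    other = sorted(set(present) - set(known))
    return known + other


@dataclass
class EvalReport:
    """Confusion matrices and accuracy summaries of one evaluation."""

    classes: list[str]
    confusion: np.ndarray  # accumulated over folds, rows true / cols predicted
    fold_confusions: list[np.ndarray] = field(default_factory=list)
    algorithm: str | None = None
    n_features: int | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def per_class_accuracy(self) -> pd.Series:
        row_sums = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = 100.0 * np.diag(self.confusion) / row_sums
        return pd.Series(acc, index=self.classes, name="accuracy_pct")

    @property
    def macro_accuracy(self) -> float:
        return float(np.nanmean(self.per_class_accuracy.to_numpy()))

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "n_features": self.n_features,
            "classes": self.classes,
            "confusion": self.confusion.astype(int).tolist(),
            "per_class_accuracy": {
                c: (None if np.isnan(v) else round(float(v), 2))
                for c, v in self.per_class_accuracy.items()
            },
            "macro_accuracy": round(self.macro_accuracy, 2),
            "warnings": self.warnings,
        }


def _confusion(classes, y_true, y_pred) -> np.ndarray:
    pos = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[pos[str(t)], pos[str(p)]] += 1
    return cm


def cross_validate(
    table: pd.DataFrame,
    algorithm: str,
    ranking: list[str],
    f: int,
    plan: FoldPlan,
) -> EvalReport:
    """Train/test the top-f features of ``ranking`` over a subject fold plan.

    A class absent from a fold's training subjects is skipped in that
    fold's model with a warning (its test windows still count as errors).
    """
    if not 1 <= f <= len(ranking):
        raise ValueError(f"f must be in [1, {len(ranking)}]")
    subset = list(ranking[:f])
    classes = _class_order(table["label"])
    subjects = set(map(str, table["subject"]))
    planned = set()
    for _, test in plan:
        planned.update(test)
    if not subjects <= planned:
        raise ValueError(
            f"subjects {sorted(subjects - planned)} missing from the fold plan"
        )

    total = np.zeros((len(classes), len(classes)), dtype=int)
    fold_cms: list[np.ndarray] = []
    notes: list[str] = []
    for train_ids, test_ids in plan:
        tr = table[table["subject"].astype(str).isin(train_ids)]
        te = table[table["subject"].astype(str).isin(test_ids)]
        if tr.empty or te.empty:
            fold_cms.append(np.zeros_like(total))
            continue
        absent = sorted(set(classes) - set(map(str, tr["label"])))
        if absent:
            msg = (
                f"classes {absent} absent from training subjects "
                f"{train_ids}; skipped in this fold's model"
            )
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
        est = make_classifier(algorithm)
        est.fit(_subset_matrix(tr, subset), tr["label"].to_numpy(object))
        pred = est.predict(_subset_matrix(te, subset))
        cm = _confusion(classes, te["label"].to_numpy(), pred)
        fold_cms.append(cm)
        total += cm
    return EvalReport(
        classes=classes,
        confusion=total,
        fold_confusions=fold_cms,
        algorithm=algorithm,
        n_features=f,
        warnings=notes,
    )


def sweep(
    table: pd.DataFrame,
    algorithms: list[str],
    ranking: list[str],
    plan: FoldPlan,
    f_values=None,
) -> pd.DataFrame:
    """Macro accuracy for every (algorithm, feature count) combination.

    Returns a DataFrame indexed by algorithm with one column per f; the
    mean over algorithms (the 'average accuracy across models' curve) is
    available as ``grid.mean(axis=0)``.
    """
    if f_values is None:
        f_values = range(1, len(ranking) + 1)
    f_values = list(f_values)
    grid = pd.DataFrame(index=list(algorithms), columns=f_values, dtype=float)
    for algo in algorithms:
        for f in f_values:
            grid.loc[algo, f] = cross_validate(
                table, algo, ranking, f, plan
            ).macro_accuracy
    return grid


def best_setting(grid: pd.DataFrame) -> tuple[str, int, float]:
    """Argmax of the sweep grid; ties prefer fewer features, then the
    algorithm listed first."""
    if grid.empty:
        raise ValueError("empty sweep grid")
    best = None
    for f in grid.columns:
        for algo in grid.index:
            acc = float(grid.loc[algo, f])
            if best is None or acc > best[2]:
                best = (str(algo), int(f), acc)
    return best


def macro_average(per_class_values) -> float:
    """Unweighted mean of per-class accuracies, rounded to 2 decimals."""
    vals = np.asarray(list(per_class_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no per-class values supplied")
    return float(round(vals.mean(), 2))


def class_accuracy_summary(report: EvalReport) -> dict:
    """Per-class accuracies plus their unweighted average (2-decimal)."""
    per_class = report.per_class_accuracy.dropna()
    return {
        **{c: float(round(v, 2)) for c, v in per_class.items()},
        "average": macro_average(per_class.to_numpy()),
    }


def best_algorithm_frequency(winners: pd.DataFrame) -> pd.Series:
    """Occurrence counts of each winning algorithm in a (position x f)
    winner table, sorted descending."""
    counts = winners.stack().value_counts()
    return counts.sort_values(ascending=False)
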