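"""Applying a pre-trained model to a differently acquired cohort.

A model trained on one scenario (device, sampling rate, subject group) is
evaluated on a second cohort after harmonizing the target signals into the
source representation: resample to the source rate, rotate into the source
frame, median-filter, and re-normalize per target subject by that
subject's own standing median. The activity schema of the evaluation is
the intersection of the two scenarios' label sets (e.g. prone is typically
dropped for elderly cohorts); model classes outside the common schema stay
in the model and count as errors if predicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import TrainedClassifier, _subset_matrix
from .evaluate import EvalReport, _class_order, _confusion
from .features import build_feature_table
from .harmonize import HarmonizationConfig, harmonize
from .recording import Recording


@dataclass
class TransferSpec:
    """Everything needed to re-deploy a trained model on a new cohort."""

    model: TrainedClassifier
    harmonization: HarmonizationConfig
    common_schema: list[str]
    window_width_s: float = 1.0
    window_step_s: float = 0.5

    def __post_init__(self) -> None:
        if not self.common_schema:
            raise ValueError("common activity schema is empty")


def apply_pretrained(spec: TransferSpec, target_recs: list[Recording]) -> EvalReport:
    """Harmonize a target cohort and evaluate the source model on it.

    Raises if any target window is labeled outside the common schema
    (the target protocol must already be restricted to it).
    """
    if not target_recs:
        raise ValueError("no target recordings supplied")
    harmonized = [harmonize(rec, spec.harmonization)[0] for rec in target_recs]
    table = build_feature_table(
        harmonized, spec.window_width_s, spec.window_step_s
    )
    schema = set(spec.common_schema)
    bad = sorted(set(map(str, table["label"])) - schema)
    if bad:
        raise ValueError(
            f"target labels {bad} are outside the common activity schema "
            f"{sorted(schema)}"
        )
    pred = spec.model.estimator.predict(_subset_matrix(table, spec.model.features))
    # report classes: common schema first, then any predicted model-only class
    classes = _class_order(spec.common_schema)
    extra = sorted(set(map(str, pred)) - set(classes))
    classes = classes + extra
    cm = _confusion(classes, table["label"].to_numpy(), pred)
    report = EvalReport(
        classes=classes,
        confusion=cm,
        fold_confusions=[cm],
        algorithm=spec.model.algorithm,
        n_features=len(spec.model.features),
    )
    return report


def top_k_overlap(ranking_a, ranking_b, k: int) -> int:
    """Size of the intersection of the first k entries of two rankings.

    Both rankings must be permutations of the same feature set; the
    overlap is symmetric and non-decreasing in k.
    """
    a, b = list(ranking_a), list(ranking_b)
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("rankings must not contain duplicates")
    if set(a) != set(b):
        raise ValueError("rankings must be permutations of the same feature set")
    if not 1 <= k <= len(a):
        raise ValueError(f"k must be in [1, {len(a)}]")
    return len(set(a[:k]) & set(b[:k]))
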