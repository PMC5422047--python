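"""Readers and writers for the pipeline artifacts.

Formats: recording CSV (``time,ax,ay,az,label``; seconds, g, activity
code), feature-table CSV (``subject,label,start_time,F1..F19``), ranking
and model JSON, cohort/harmonization YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import KNNClassifier, NaiveBayesClassifier, TrainedClassifier
from .features import FEATURE_NAMES, META_COLUMNS
from .harmonize import HarmonizationConfig, rotation_from_axes
from .recording import ACTIVITIES, Recording
from .relieff import ReliefFResult
from .siggen import ActivityProfile, CohortSpec, default_profiles

RECORDING_COLUMNS = ("time", "ax", "ay", "az", "label")


# --------------------------------------------------------------------------
# recordings

def write_recording(rec: Recording, path) -> None:
    df = pd.DataFrame(
        {
            "time": rec.time,
            "ax": rec.acc[:, 0],
            "ay": rec.acc[:, 1],
            "az": rec.acc[:, 2],
            "label": rec.labels,
        }
    )
    df.to_csv(path, index=False)


def read_recording(path, subject_id: str | None = None, known_labels=None) -> Recording:
    """Read a recording CSV; the sampling rate is inferred as the
    reciprocal of the median inter-sample interval.

    Errors carry 1-based file line numbers (header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if tuple(df.columns) != RECORDING_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(RECORDING_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if df.empty:
        raise ValueError(f"{path}: no samples")
    for col in ("time", "ax", "ay", "az"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            line = int(numeric.isna().idxmax()) + 2
            raise ValueError(f"{path}:{line}: malformed value in column {col!r}")
        df[col] = numeric
    t = df["time"].to_numpy(float)
    if len(t) >= 2:
        diffs = np.diff(t)
        if np.any(diffs <= 0):
            line = int(np.argmax(diffs <= 0)) + 3  # second row of the pair
            raise ValueError(f"{path}:{line}: time is not strictly increasing")
        rate = 1.0 / float(np.median(diffs))
    else:
        rate = 1.0
    allowed = set(known_labels) if known_labels is not None else set(ACTIVITIES)
    labels = df["label"].astype(str).to_numpy(object)
    unknown = ~np.isin(labels, sorted(allowed))
    if unknown.any():
        line = int(np.argmax(unknown)) + 2
        raise ValueError(
            f"{path}:{line}: unknown activity label {labels[unknown][0]!r}"
        )
    return Recording(
        time=t,
        acc=df[["ax", "ay", "az"]].to_numpy(float),
        labels=labels,
        rate=rate,
        subject_id=subject_id or path.stem,
    )


# --------------------------------------------------------------------------
# feature tables

def write_feature_table(table: pd.DataFrame, path) -> None:
    table[list(META_COLUMNS) + list(FEATURE_NAMES)].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = list(META_COLUMNS) + list(FEATURE_NAMES)
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    return df


# --------------------------------------------------------------------------
# rankings

def write_ranking(result: ReliefFResult, path) -> None:
    payload = {
        "ranking": result.ranking,
        "weights": result.weights,
        "n": result.n,
        "params": result.params,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ranking(path) -> ReliefFResult:
    payload = json.loads(Path(path).read_text())
    return ReliefFResult(
        weights=payload["weights"],
        ranking=payload["ranking"],
        n=payload["n"],
        params=payload.get("params", {}),
    )


# --------------------------------------------------------------------------
# models (native algorithms only)

def save_model(model: TrainedClassifier, path) -> None:
    est = model.estimator
    if isinstance(est, NaiveBayesClassifier):
        params = {
            "classes": list(map(str, est.classes_)),
            "priors": est.priors_.tolist(),
            "theta": est.theta_.tolist(),
            "var": est.var_.tolist(),
            "var_floor": est.var_floor,
        }
    elif isinstance(est, KNNClassifier):
        params = {
            "classes": list(map(str, est.classes_)),
            "n_neighbors": est.n_neighbors,
            "min": est.min_.tolist(),
            "scale": est.scale_.tolist(),
            "train_scaled": est._Z.tolist(),
            "train_class_idx": est._y_idx.tolist(),
        }
    else:
        raise ValueError(
            f"cannot serialize a {type(est).__name__}; only native NB/kNN "
            "models have a JSON form"
        )
    payload = {
        "algorithm": model.algorithm,
        "features": model.features,
        "params": params,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path) -> TrainedClassifier:
    payload = json.loads(Path(path).read_text())
    algo, params = payload["algorithm"], payload["params"]
    if algo == "NB":
        est = NaiveBayesClassifier(var_floor=params["var_floor"])
        est.classes_ = np.asarray(params["classes"], dtype=object)
        est.priors_ = np.asarray(params["priors"], float)
        est.theta_ = np.asarray(params["theta"], float)
        est.var_ = np.asarray(params["var"], float)
        est.n_features_in_ = est.theta_.shape[1]
    elif algo.endswith("NN"):
        est = KNNClassifier(n_neighbors=params["n_neighbors"])
        est.classes_ = np.asarray(params["classes"], dtype=object)
        est.min_ = np.asarray(params["min"], float)
        est.scale_ = np.asarray(params["scale"], float)
        est._Z = np.asarray(params["train_scaled"], float)
        est._y_idx = np.asarray(params["train_class_idx"], int)
        est.n_features_in_ = est._Z.shape[1]
    else:
        raise ValueError(f"cannot load algorithm {algo!r} from JSON")
    return TrainedClassifier(algo, payload["features"], est)


# --------------------------------------------------------------------------
# YAML configuration

def _rotation_from_config(value) -> np.ndarray:
    if value is None or value == "identity":
        return np.eye(3)
    if isinstance(value, dict) and "axes" in value:
        return rotation_from_axes(tuple(value["axes"]))
    mat = np.asarray(value, dtype=float)
    if mat.size == 9:
        return mat.reshape(3, 3)
    raise ValueError("rotation must be 'identity', {axes: [..]} or 9 numbers")


def cohort_from_dict(d: dict) -> CohortSpec:
    activities = d.get("activities")
    if activities is None:
        profiles = default_profiles(duration_s=float(d.get("duration_s", 15.0)))
    elif all(isinstance(a, str) for a in activities):
        profiles = default_profiles(
            tuple(activities), duration_s=float(d.get("duration_s", 15.0))
        )
    else:
        profiles = [
            ActivityProfile(
                label=a["label"],
                gravity_dir=tuple(a["gravity"]),
                osc_amplitude=float(a.get("osc_amplitude", 0.0)),
                osc_freq=float(a.get("osc_freq", 0.0)),
                duration_s=float(a.get("duration_s", 15.0)),
            )
            for a in activities
        ]
    return CohortSpec(
        n_subjects=int(d.get("n_subjects", 12)),
        activities=profiles,
        sampling_rate_hz=float(d.get("sampling_rate_hz", 15.0)),
        device_rotation=_rotation_from_config(d.get("rotation")),
        noise_sd=float(d.get("noise_sd", 0.05)),
        subject_offset_sd=float(d.get("subject_offset_sd", 0.05)),
        seed=int(d.get("seed", 0)),
    )


def read_cohort_yaml(path) -> CohortSpec:
    return cohort_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def harmonization_from_dict(d: dict) -> HarmonizationConfig:
    return HarmonizationConfig(
        target_rate_hz=float(d.get("target_rate_hz", 15.0)),
        rotation=_rotation_from_config(d.get("rotation")),
        median_kernel=int(d.get("median_kernel", 3)),
        normalize=bool(d.get("normalize", True)),
    )


def read_harmonization_yaml(path) -> HarmonizationConfig:
    return harmonization_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def write_report(report_dict: dict, path) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=2))
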