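"""Sliding-window segmentation and the 19 windowed time-domain features.

A normalized recording is cut into fixed-width windows (default 1 s,
shifted by 0.5 s), each window carrying a single activity label, and every
window is summarised by 19 statistics of its tri-axial samples:

========  ==============================================================
F1-F3     means mu along x, y, z
F4-F6     standard deviations sigma along x, y, z (population form, /N)
F7-F9     maxima M along x, y, z
F10-F12   minima m along x, y, z
F13-F15   ranges M - m along x, y, z
F16       standard-deviation magnitude sqrt(sigma_x^2+sigma_y^2+sigma_z^2)
F17-F19   Pearson correlations r_xy, r_xz, r_yz (= sigma_ab/(sigma_a
          sigma_b), 0 when either axis has zero variance)
========  ==============================================================

Windows are laid independently within each contiguous same-label segment,
restarting at the segment's first sample, so no window ever straddles an
activity transition. At 15 Hz the 0.5 s shift is a non-integer 7.5
samples; the step is fixed at round(step x rate) = 8 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import Recording

#: Feature names in canonical order.
FEATURE_NAMES: tuple[str, ...] = tuple(f"F{i}" for i in range(1, 20))

#: Metadata columns of a feature table, ahead of F1..F19.
META_COLUMNS: tuple[str, ...] = ("subject", "label", "start_time")

_AXIS_PAIRS = ((0, 1), (0, 2), (1, 2))  # x-y, x-z, y-z


@dataclass(frozen=True)
class Window:
    """One single-label window of consecutive samples."""

    samples: np.ndarray  # (n, 3)
    label: str
    subject_id: str
    start_time: float

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("window samples must have shape (n, 3)")
        if self.samples.shape[0] < 2:
            raise ValueError("a window needs at least 2 samples")


def segment_windows(
    rec: Recording, width_s: float = 1.0, step_s: float = 0.5
) -> list[Window]:
    """Cut a recording into fixed single-label windows.

    Window width and step are converted to whole samples by rounding at the
    recording's rate. Windows are placed within each contiguous label run,
    so a 15 s activity segment at 15 Hz with a 1 s window and 8-sample step
    yields floor((225-15)/8)+1 = 27 windows.
    """
    if not (width_s > 0 and step_s > 0):
        raise ValueError("window width and step must be positive")
    w = int(round(width_s * rec.rate))
    s = max(int(round(step_s * rec.rate)), 1)
    if w < 2:
        raise ValueError(
            f"window of {width_s} s is shorter than 2 samples at "
            f"{rec.rate} Hz"
        )
    out: list[Window] = []
    for a, b, label in rec.label_runs():
        for start in range(a, b - w + 1, s):
            out.append(
                Window(
                    samples=rec.acc[start : start + w],
                    label=label,
                    subject_id=rec.subject_id,
                    start_time=float(rec.time[start]),
                )
            )
    return out


def _feature_block(X: np.ndarray) -> np.ndarray:
    """Vectorised feature computation for a stack of windows (W, n, 3)."""
    mu = X.mean(axis=1)
    sd = X.std(axis=1)  # population (divide by N)
    mx = X.max(axis=1)
    mn = X.min(axis=1)
    rng = mx - mn
    sd_mag = np.sqrt((sd**2).sum(axis=1, keepdims=True))
    centered = X - mu[:, None, :]
    corrs = []
    for a, b in _AXIS_PAIRS:
        cov = (centered[:, :, a] * centered[:, :, b]).mean(axis=1)
        denom = sd[:, a] * sd[:, b]
        corrs.append(np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0))
    return np.hstack([mu, sd, mx, mn, rng, sd_mag, np.column_stack(corrs)])


def compute_features(window: Window) -> np.ndarray:
    """The 19-feature vector of one window, in FEATURE_NAMES order."""
    return _feature_block(window.samples[None, :, :])[0]


def build_feature_table(
    recs: list[Recording], width_s: float = 1.0, step_s: float = 0.5
) -> pd.DataFrame:
    """Feature table over a cohort: one row per window.

    Columns are ``subject, label, start_time, F1..F19``; rows are ordered
    by recording (subject) and then window start time.
    """
    if not recs:
        raise ValueError("no recordings supplied")
    frames = []
    for rec in recs:
        wins = segment_windows(rec, width_s, step_s)
        if not wins:
            continue
        X = np.stack([w.samples for w in wins])
        feats = _feature_block(X)
        df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
        df.insert(0, "start_time", [w.start_time for w in wins])
        df.insert(0, "label", [w.label for w in wins])
        df.insert(0, "subject", rec.subject_id)
        frames.append(df)
    if not frames:
        raise ValueError("no windows produced from the supplied recordings")
    table = pd.concat(frames, ignore_index=True)
    if table[list(FEATURE_NAMES)].isna().any().any():
        raise AssertionError("feature table contains missing values")
    return table
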