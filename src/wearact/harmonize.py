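"""Cross-device signal harmonization.

Recordings acquired with different hardware differ in sampling rate, axis
frame, noise and baseline. Harmonization maps them to a common reference
representation in four steps, applied in this order:

1. **resample** — linear interpolation down to the target rate (the
   reference pipeline only down-samples; 50 -> 15 Hz is a non-integer
   ratio, so interpolation at exact target-period times is used instead of
   decimation);
2. **rotate** — an orthonormal transformation aligning the device axes with
   the reference frame;
3. **median filter** — a short running median per axis against impulsive
   noise;
4. **normalize** — subtract the per-axis median of the samples labeled
   ``standing``, removing subject- and mounting-specific baselines.

Rotation and linear-interpolation resampling commute; normalization comes
last so that the standing reference lives in the final frame. The standing
reference is computed per subject, since inter-subject variation is exactly
what it is meant to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter as _nd_median_filter

from .recording import Recording
from .siggen import _check_rotation

_AXIS_VECS = {
    "x": (1.0, 0.0, 0.0),
    "y": (0.0, 1.0, 0.0),
    "z": (0.0, 0.0, 1.0),
    "-x": (-1.0, 0.0, 0.0),
    "-y": (0.0, -1.0, 0.0),
    "-z": (0.0, 0.0, -1.0),
}


def rotation_from_axes(axes: tuple[str, str, str]) -> np.ndarray:
    """Axis-permutation rotation preset.

    ``axes[i]`` names the reference-frame direction that device axis i
    points along, e.g. ``("y", "-x", "z")`` for a device whose x axis points
    along reference y and whose y axis points along reference -x. The
    returned matrix maps device-frame vectors into the reference frame.
    """
    try:
        cols = [_AXIS_VECS[a.strip().lower()] for a in axes]
    except KeyError as exc:
        raise ValueError(f"unknown axis token {exc.args[0]!r}") from exc
    return _check_rotation(np.array(cols, dtype=float).T)


@dataclass
class HarmonizationConfig:
    """Parameters of the four-step harmonization pipeline."""

    target_rate_hz: float = 15.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    median_kernel: int = 3
    normalize: bool = True

    def __post_init__(self) -> None:
        if not self.target_rate_hz > 0:
            raise ValueError("target_rate_hz must be positive")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be an odd positive integer")
        self.rotation = _check_rotation(self.rotation)


@dataclass(frozen=True)
class StandingReference:
    """Per-axis median of the standing-labeled samples of one subject (g)."""

    median: tuple[float, float, float]
    subject_id: str


def resample(rec: Recording, target_rate_hz: float) -> Recording:
    """Down-sample by linear interpolation at exact target-period times.

    Sample values are interpolated per axis; each new sample takes the
    label of the nearest original sample (earlier sample on a tie). The
    recorded duration is preserved to within one sample period.
    """
    if not target_rate_hz > 0:
        raise ValueError("target rate must be positive")
    if target_rate_hz > rec.rate * (1 + 1e-9):
        raise ValueError(
            f"cannot up-sample: target {target_rate_hz} Hz exceeds source "
            f"{rec.rate} Hz"
        )
    if abs(target_rate_hz - rec.rate) <= 1e-9 * rec.rate:
        return rec.copy()
    t0, t1 = rec.time[0], rec.time[-1]
    n_new = int(np.floor((t1 - t0) * target_rate_hz)) + 1
    t_new = t0 + np.arange(n_new) / target_rate_hz
    acc = np.column_stack(
        [np.interp(t_new, rec.time, rec.acc[:, k]) for k in range(3)]
    )
    # nearest original sample per new time; ties resolve to the earlier one
    right = np.searchsorted(rec.time, t_new, side="left")
    right = np.clip(right, 1, len(rec) - 1)
    left = right - 1
    pick_right = (rec.time[right] - t_new) < (t_new - rec.time[left])
    nearest = np.where(pick_right, right, left)
    return Recording(
        time=t_new,
        acc=acc,
        labels=rec.labels[nearest],
        rate=target_rate_hz,
        subject_id=rec.subject_id,
        meta=dict(rec.meta),
    )


def apply_rotation(rec: Recording, rotation: np.ndarray) -> Recording:
    """Rotate every sample vector into the reference frame."""
    rotation = _check_rotation(rotation)
    out = rec.copy()
    out.acc = rec.acc @ rotation.T
    return out


def median_filter(rec: Recording, kernel: int) -> Recording:
    """Per-axis running median with edge replication; labels unchanged."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd and >= 1, got {kernel}")
    out = rec.copy()
    if kernel > 1:
        out.acc = _nd_median_filter(rec.acc, size=(kernel, 1), mode="nearest")
    return out


def standing_reference(rec: Recording) -> StandingReference:
    mask = rec.labels == "standing"
    if not np.any(mask):
        raise ValueError(
            f"no standing-labeled samples for subject {rec.subject_id}; "
            "cannot compute the normalization reference"
        )
    med = np.median(rec.acc[mask], axis=0)
    return StandingReference(tuple(float(v) for v in med), rec.subject_id)


def normalize_standing(rec: Recording) -> tuple[Recording, StandingReference]:
    """Subtract the subject's standing-posture per-axis median."""
    ref = standing_reference(rec)
    out = rec.copy()
    out.acc = rec.acc - np.asarray(ref.median)
    return out, ref


def harmonize(
    rec: Recording, config: HarmonizationConfig
) -> tuple[Recording, StandingReference | None]:
    """Full pipeline: resample -> rotate -> median filter -> normalize."""
    out = resample(rec, config.target_rate_hz)
    out = apply_rotation(out, config.rotation)
    out = median_filter(out, config.median_kernel)
    if config.normalize:
        return normalize_standing(out)
    return out, None
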