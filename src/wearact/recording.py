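"""Core container for a labeled tri-axial acceleration stream.

A :class:`Recording` holds one subject's signal from one device position:
sample times (s), acceleration vectors in the device frame (units of g,
gravity included), a per-sample activity label, and the nominal sampling
rate. All downstream stages (harmonization, windowed feature extraction)
consume and produce this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical activity schema, in fixed order. This order is used for
#: deterministic tie-breaking in classifiers and for report layout.
ACTIVITIES: tuple[str, ...] = (
    "sitting",
    "supine",
    "lying_left",
    "prone",
    "lying_right",
    "standing",
    "walking",
)


@dataclass
class Recording:
    """Labeled tri-axial acceleration stream for one subject/position.

    Parameters
    ----------
    time : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    acc : ndarray, shape (n, 3)
        Acceleration in g along the device x, y, z axes (gravity included).
    labels : ndarray of str, shape (n,)
        Activity code of each sample.
    rate : float
        Nominal sampling rate in Hz.
    subject_id : str
        Identifier of the wearer.
    """

    time: np.ndarray
    acc: np.ndarray
    labels: np.ndarray
    rate: float
    subject_id: str = "S00"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError(f"acc must have shape (n, 3), got {self.acc.shape}")
        n = self.acc.shape[0]
        if self.time.shape != (n,) or self.labels.shape != (n,):
            raise ValueError("time, acc and labels must have matching lengths")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return self.acc.shape[0]

    @property
    def duration(self) -> float:
        """Span of sample times in seconds."""
        return float(self.time[-1] - self.time[0]) if len(self) else 0.0

    def copy(self) -> "Recording":
        return replace(
            self,
            time=self.time.copy(),
            acc=self.acc.copy(),
            labels=self.labels.copy(),
            meta=dict(self.meta),
        )

    def label_runs(self) -> list[tuple[int, int, str]]:
        """Contiguous same-label segments as ``(start, stop, label)`` slices."""
        if len(self) == 0:
            return []
        change = np.flatnonzero(self.labels[1:] != self.labels[:-1]) + 1
        bounds = np.concatenate(([0], change, [len(self)]))
        return [
            (int(a), int(b), str(self.labels[a]))
            for a, b in zip(bounds[:-1], bounds[1:])
        ]
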