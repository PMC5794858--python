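"""Shared data model for the interval-timing ERP pipeline.

The pipeline operates on three containers:

``ContinuousRecording``
    A multichannel scalp EEG signal (channels x samples, µV) with a sampling
    rate, a list of event markers (stimulus / response / feedback) and an
    electrode :class:`Montage`.
``Epochs``
    Trials x channels x samples cut around a lock event, with a millisecond
    time axis, per-trial metadata (reaction time, trial category, kept flag)
    and a units tag that tracks whether data are raw potentials (µV) or
    current source density (µV/m²).
``SubjectRecord``
    One subject: group label, symptom-checklist scores and the recording.

Conventions
-----------
* Latencies are in milliseconds relative to the lock event; analysis windows
  ``[a, b]`` are closed intervals including both boundary samples (boundary
  sample = :func:`ms_to_samples` of the boundary latency).
* Electrode positions live on the unit sphere, right-handed, vertex at
  ``(0, 0, 1)``; the head radius enters only through the CSD scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_CHANNELS",
    "TrialCategory",
    "Montage",
    "Event",
    "ContinuousRecording",
    "Epochs",
    "SubjectRecord",
    "make_equidistant_montage",
    "ms_to_samples",
    "window_indices",
]

#: Channels every montage must carry: vertex (CNV), fronto-central (FRN) and
#: the four posterior-lateral sites used for P1/N1.
REQUIRED_CHANNELS = ("Cz", "FCz", "P7", "P8", "P9", "P10")


class TrialCategory(str, Enum):
    """Response classification for one trial of the 1200-ms time-production task."""

    CORRECT = "correct"
    EARLY = "early"
    LATE = "late"
    MISS = "miss"


class MontageError(ValueError):
    """Raised for invalid electrode layouts."""


@dataclass(frozen=True)
class Montage:
    """Labeled electrode geometry on the unit sphere.

    Parameters
    ----------
    labels : list of str
        Unique channel names; must include :data:`REQUIRED_CHANNELS`.
    positions : ndarray, shape (n_channels, 3)
        Unit-norm 3D coordinates, vertex at ``(0, 0, 1)``.
    reference_label : str
        Name of the recording reference site (not itself a data channel).
    """

    labels: tuple
    positions: np.ndarray
    reference_label: str = "Fpz"

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(labels)) != len(labels):
            raise MontageError("channel labels must be unique")
        if pos.shape != (len(labels), 3):
            raise MontageError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise MontageError("electrode positions must have unit norm")
        missing = [c for c in REQUIRED_CHANNELS if c not in labels]
        if missing:
            raise MontageError(f"montage is missing required channels: {missing}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def to_table(self) -> pd.DataFrame:
        """Serialize as a plain-text table: label, x, y, z."""
        return pd.DataFrame(self.positions, columns=["x", "y", "z"]).assign(
            label=list(self.labels)
        )[["label", "x", "y", "z"]]

    @classmethod
    def from_table(cls, table: pd.DataFrame, reference_label: str = "Fpz") -> "Montage":
        return cls(
            labels=tuple(table["label"]),
            positions=table[["x", "y", "z"]].to_numpy(float),
            reference_label=reference_label,
        )


@dataclass(frozen=True)
class Event:
    """A marker in a continuous recording."""

    onset_sample: int
    kind: str  # "stimulus" | "response" | "feedback"
    trial_index: int

    def __post_init__(self):
        if self.kind not in ("stimulus", "response", "feedback"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")


@dataclass
class ContinuousRecording:
    """Channels x samples scalp signal in µV with event markers."""

    data: np.ndarray
    rate: float
    events: list
    montage: Montage

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.montage):
            raise ValueError("channel count must equal montage size")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        n = self.data.shape[1]
        for ev in self.events:
            if not (0 <= ev.onset_sample < n):
                raise ValueError(f"event at sample {ev.onset_sample} outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def events_of(self, kind: str) -> list:
        return [ev for ev in self.events if ev.kind == kind]


@dataclass
class Epochs:
    """Trials x channels x samples relative to a lock event.

    ``trial_meta`` is a DataFrame with one row per trial carrying at least
    ``rt_ms``, ``category`` and ``kept``; feedback-locked epochs additionally
    carry ``condition`` ("correct" vs "error").  ``units_tag`` is one of
    ``"µV"``, ``"µV/m²"`` or ``"µV/m² (nominal)"`` (identity spatial mode).
    """

    data: np.ndarray
    times_ms: np.ndarray
    lock: str
    rate: float
    ch_names: tuple
    trial_meta: pd.DataFrame
    baseline_applied: bool = False
    units_tag: str = "µV"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.ch_names = tuple(self.ch_names)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time axis does not match times_ms")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta length must equal trial count")
        steps = np.diff(self.times_ms)
        if self.times_ms.size > 1:
            if np.any(steps <= 0) or not np.allclose(steps, 1000.0 / self.rate):
                raise ValueError("times_ms must increase uniformly at 1000/rate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel(self, label: str) -> int:
        return self.ch_names.index(label)

    def lock_index(self) -> int:
        """Index of the sample at latency 0 (the lock event)."""
        idx = int(np.argmin(np.abs(self.times_ms)))
        if abs(self.times_ms[idx]) > 1e-6:
            raise ValueError("epoch time axis does not contain latency 0")
        return idx

    def select(self, mask: np.ndarray) -> "Epochs":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            data=self.data[mask],
            trial_meta=self.trial_meta.loc[mask].reset_index(drop=True),
        )


@dataclass
class SubjectRecord:
    """One simulated or recorded subject."""

    subject_id: str
    group: str  # "control" | "ADD" | "ADHD-C"
    symptom_scores: tuple  # (inattention, hyperactivity, impulsivity), each 0..3
    recording: ContinuousRecording | None = None

    def __post_init__(self):
        if self.group not in ("control", "ADD", "ADHD-C"):
            raise ValueError(f"unknown group {self.group!r}")
        if len(self.symptom_scores) != 3:
            raise ValueError("symptom_scores must be a 3-tuple")
        for s in self.symptom_scores:
            if not (0.0 <= s <= 3.0):
                raise ValueError("symptom scores must lie in [0, 3]")


def ms_to_samples(t_ms: float, rate: float) -> int:
    """Convert a latency in ms to a sample offset (round half away from zero).

    >>> ms_to_samples(1000, 256)
    256
    >>> ms_to_samples(-200, 256)
    -51
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    x = t_ms * rate / 1000.0
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def window_indices(lock_index: int, window_ms: Sequence[float], rate: float) -> slice:
    """Slice of epoch samples for the closed latency window ``[a, b]``."""
    a, b = window_ms
    if not a < b:
        raise ValueError("window start must precede window end")
    return slice(lock_index + ms_to_samples(a, rate), lock_index + ms_to_samples(b, rate) + 1)


def _fibonacci_upper_sphere(n: int, z_min: float = -0.2) -> np.ndarray:
    """Deterministic near-equidistant point set on the sphere cap ``z > z_min``.

    Golden-angle spiral mapped onto the cap, densest-packing style.  The cap
    restriction reflects that scalp electrodes do not cover the lower head.
    """
    k = np.arange(n)
    # uniform in z over the cap, golden-angle in azimuth
    z = 1.0 - (1.0 - z_min) * (k + 0.5) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_equidistant_montage(n_channels: int = 60) -> Montage:
    """Build a deterministic approximately-equidistant scalp montage.

    Realizes an n-channel layout on the upper unit sphere via a golden-angle
    spiral and assigns the six analysis channels to the geometrically
    appropriate sites: Cz at the vertex, FCz on the anterior midline just in
    front of it, and P7/P8/P9/P10 at posterior-lateral positions (+y is
    anterior, +x is right).

    Parameters
    ----------
    n_channels : int
        Number of scalp channels, at least 16 (default 60).
    """
    if n_channels < 16:
        raise MontageError("montage needs at least 16 channels")
    pts = _fibonacci_upper_sphere(n_channels)

    def _nearest(target, taken):
        d = np.linalg.norm(pts - np.asarray(target), axis=1)
        d[list(taken)] = np.inf
        return int(np.argmin(d))

    # idealized sites for the named channels (unit vectors)
    s2 = math.sqrt(0.5)
    targets = {
        "Cz": (0.0, 0.0, 1.0),
        "FCz": (0.0, 0.35, 0.94),
        "P7": (-0.80, -0.45, 0.40),
        "P8": (0.80, -0.45, 0.40),
        "P9": (-s2, -s2, 0.05),
        "P10": (s2, -s2, 0.05),
    }
    labels = [f"E{i + 1}" for i in range(n_channels)]
    taken: set = set()
    for name, tgt in targets.items():
        idx = _nearest(np.asarray(tgt) / np.linalg.norm(tgt), taken)
        labels[idx] = name
        taken.add(idx)
    return Montage(labels=tuple(labels), positions=pts)
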