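"""Core domain types shared across the pipeline.

The five postural categories follow the thigh-inclinometer convention used as
ground truth throughout: sitting, standing, stepping, plus the two brief
postural-change classes (sit-to-stand and stand-to-sit) that delimit sitting
bouts.  The fixed class order defined here (SIT < STAND < STEP < SIT_TO_STAND
< STAND_TO_SIT) is the canonical order for probability vectors, confusion
matrices and all tie-breaking rules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PostureClass",
    "CLASS_ORDER",
    "CLASS_NAMES",
    "NONTRANSITION_CLASSES",
    "UPRIGHT_CLASSES",
    "TriaxialRecording",
    "ActivPALEvent",
    "SecondLabelSeries",
    "EpochCountSeries",
    "ACTIVITY_CODES",
]


class PostureClass(enum.IntEnum):
    """The closed five-class label set.  Integer values are positional."""

    SIT = 0
    STAND = 1
    STEP = 2
    SIT_TO_STAND = 3
    STAND_TO_SIT = 4

    @property
    def is_transition(self) -> bool:
        return self in (PostureClass.SIT_TO_STAND, PostureClass.STAND_TO_SIT)


CLASS_ORDER: tuple[PostureClass, ...] = tuple(PostureClass)
CLASS_NAMES: tuple[str, ...] = tuple(c.name for c in CLASS_ORDER)
NONTRANSITION_CLASSES: tuple[PostureClass, ...] = (
    PostureClass.SIT,
    PostureClass.STAND,
    PostureClass.STEP,
)
UPRIGHT_CLASSES: frozenset[PostureClass] = frozenset(
    {PostureClass.STAND, PostureClass.STEP}
)

#: activity codes appearing in thigh-inclinometer event files
ACTIVITY_CODES: tuple[str, ...] = ("sedentary", "standing", "stepping")


def _as_timestamp(value) -> pd.Timestamp:
    ts = pd.Timestamp(value)
    if ts is pd.NaT:
        raise ValueError(f"invalid timestamp: {value!r}")
    return ts


@dataclass
class TriaxialRecording:
    """One participant-day of raw triaxial acceleration in g units.

    Axes are the device axes of a hip-worn accelerometer; samples are taken
    at ``sampling_rate_hz`` (30 Hz for the devices this models).
    """

    participant_id: str
    start_time: pd.Timestamp
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        self.start_time = _as_timestamp(self.start_time)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal length")
        if len(self.x) == 0:
            raise ValueError("recording is empty")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite sample in axis {name}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return len(self.x) / self.sampling_rate_hz


@dataclass(frozen=True)
class ActivPALEvent:
    """A single posture interval from a thigh-inclinometer event file."""

    start_time: pd.Timestamp
    duration_s: float
    activity: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_time", _as_timestamp(self.start_time))
        if not self.duration_s > 0:
            raise ValueError(f"event duration must be positive, got {self.duration_s}")
        if self.activity not in ACTIVITY_CODES:
            raise ValueError(f"unknown activity code {self.activity!r}")

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=float(self.duration_s))


@dataclass
class SecondLabelSeries:
    """Per-second posture labels, one :class:`PostureClass` value per second.

    ``excluded`` marks seconds outside device wear (a non-wear sentinel); the
    label stored for an excluded second is a placeholder and must be ignored
    by training, testing and bout detection.
    """

    start_time: pd.Timestamp
    labels: np.ndarray
    excluded: np.ndarray | None = None
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.start_time = _as_timestamp(self.start_time)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.size == 0:
            raise ValueError("empty label series")
        if self.excluded is None:
            self.excluded = np.zeros(self.labels.size, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.size != self.labels.size:
                raise ValueError("excluded mask length mismatch")
        valid = self.labels[~self.excluded]
        if valid.size and (valid.min() < 0 or valid.max() > 4):
            raise ValueError("labels must be one of the five posture classes")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class EpochCountSeries:
    """Per-minute vertical-axis activity counts, as exported at the minute level."""

    participant_id: str
    start_time: pd.Timestamp
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = _as_timestamp(self.start_time)
        counts = np.asarray(self.counts)
        if counts.size == 0:
            raise ValueError("empty count series")
        if not np.all(np.isfinite(counts.astype(float))):
            raise ValueError("non-finite count")
        as_int = counts.astype(np.int64)
        if np.any(counts.astype(float) != as_int):
            raise ValueError("counts must be integer-valued")
        if np.any(as_int < 0):
            raise ValueError("counts must be non-negative")
        self.counts = as_int

    def __len__(self) -> int:
        return len(self.counts)
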