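"""Readers and writers for the delimited-text formats used by the pipeline.

Four file families are handled:

* raw triaxial recordings — one sample per row, columns ``x,y,z`` in g, with
  ``# key=value`` header lines carrying participant id, start time and
  sampling rate;
* thigh-inclinometer ("activPAL"-style) event files — columns
  ``start_time,duration_s,activity_code``;
* per-minute vertical-axis epoch counts — ``# key=value`` header plus a
  ``count`` column;
* posture sequences — per-5-s-window labels with optional class
  probabilities.

Ground-truth derivation lives here too: :func:`events_to_second_labels`
assigns one posture label per second from an event file and inserts the
1-second transition classes at every sitting/upright boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ACTIVITY_CODES,
    CLASS_NAMES,
    ActivPALEvent,
    EpochCountSeries,
    PostureClass,
    SecondLabelSeries,
    TriaxialRecording,
)

__all__ = [
    "RawDialect",
    "ParseError",
    "read_raw_recording",
    "write_raw_recording",
    "read_activpal_events",
    "write_activpal_events",
    "events_to_second_labels",
    "read_epoch_counts",
    "write_epoch_counts",
    "read_second_labels",
    "write_second_labels",
    "read_posture_sequence",
    "write_posture_sequence",
]


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass
class RawDialect:
    """Configuration for raw-recording files.

    Device exports vary; the default dialect is comma-delimited ``x,y,z``
    rows preceded by ``# key=value`` header lines.  Metadata supplied here
    overrides (or substitutes for) the file header.
    """

    delimiter: str = ","
    participant_id: str | None = None
    start_time: object | None = None
    sampling_rate_hz: float | None = None


def _read_header_comments(path: Path) -> tuple[dict, int]:
    """Return ``# key=value`` metadata and the number of leading comment lines."""
    meta: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta, n


def read_raw_recording(path, dialect: RawDialect | None = None) -> TriaxialRecording:
    """Read a raw triaxial recording from delimited text.

    Raises :class:`ParseError` naming the line number for malformed or
    non-numeric rows, and ``ValueError`` for non-finite samples.
    """
    path = Path(path)
    dialect = dialect or RawDialect()
    meta, n_comments = _read_header_comments(path)

    df = pd.read_csv(path, comment="#", sep=dialect.delimiter)
    expected = ["x", "y", "z"]
    if list(df.columns[:3]) != expected:
        raise ParseError(f"{path}: expected columns x,y,z, got {list(df.columns)}")
    data = {}
    for col in expected:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna().to_numpy())
        if bad.size:
            # file line = comments + column header + 1-based data row
            line_no = n_comments + 1 + int(bad[0]) + 1
            raise ParseError(f"{path}: malformed value in column {col} at line {line_no}")
        data[col] = coerced.to_numpy(dtype=float)

    pid = dialect.participant_id or meta.get("participant_id", "")
    start = dialect.start_time or meta.get("start_time")
    if start is None:
        raise ParseError(f"{path}: no start_time in header and none supplied")
    rate = dialect.sampling_rate_hz or float(meta.get("sampling_rate_hz", 0) or 0)
    if not rate:
        raise ParseError(f"{path}: no sampling_rate_hz in header and none supplied")
    return TriaxialRecording(
        participant_id=pid,
        start_time=start,
        x=data["x"],
        y=data["y"],
        z=data["z"],
        sampling_rate_hz=float(rate),
    )


def write_raw_recording(rec: TriaxialRecording, path, decimals: int = 6) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# participant_id={rec.participant_id}\n")
        fh.write(f"# start_time={rec.start_time.isoformat()}\n")
        fh.write(f"# sampling_rate_hz={rec.sampling_rate_hz:g}\n")
        fh.write("x,y,z\n")
        fmt = f"%.{decimals}f"
        np.savetxt(fh, np.column_stack([rec.x, rec.y, rec.z]), fmt=fmt, delimiter=",")


def read_activpal_events(path) -> list[ActivPALEvent]:
    """Read an event file; validates ordering, positivity and activity codes."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"start_time", "duration_s", "activity_code"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    events: list[ActivPALEvent] = []
    for i, row in enumerate(df.itertuples(index=False)):
        code = str(row.activity_code)
        if code not in ACTIVITY_CODES:
            raise ValueError(f"{path}: unknown activity code {code!r} in row {i + 1}")
        dur = float(row.duration_s)
        if not dur > 0:
            raise ValueError(f"{path}: non-positive duration in row {i + 1}")
        events.append(ActivPALEvent(row.start_time, dur, code))
    _validate_event_sequence(events)
    return events


def _validate_event_sequence(events: list[ActivPALEvent]) -> None:
    for prev, cur in zip(events, events[1:]):
        if cur.start_time < prev.start_time:
            raise ValueError("events out of time order")
        if cur.start_time < prev.end_time - pd.Timedelta(microseconds=1):
            raise ValueError(
                f"overlapping events at {prev.start_time} and {cur.start_time}"
            )


def write_activpal_events(events: list[ActivPALEvent], path) -> None:
    df = pd.DataFrame(
        {
            "start_time": [e.start_time.isoformat() for e in events],
            "duration_s": [e.duration_s for e in events],
            "activity_code": [e.activity for e in events],
        }
    )
    df.to_csv(path, index=False)


_ACTIVITY_TO_CLASS = {
    "sedentary": PostureClass.SIT,
    "standing": PostureClass.STAND,
    "stepping": PostureClass.STEP,
}

#: events closer than this (seconds) are considered contiguous
_GAP_TOL_S = 1e-6


def events_to_second_labels(
    events: list[ActivPALEvent],
    gap_policy: str = "error",
) -> SecondLabelSeries:
    """Assign one posture label per second from an ordered event list.

    Sedentary seconds become SIT, standing STAND and stepping STEP.  At each
    boundary where a sedentary event meets an upright one, the first second
    of the succeeding event is relabeled with the corresponding transition
    class (SIT_TO_STAND when sitting precedes, STAND_TO_SIT when sitting
    follows); standing/stepping boundaries produce no transition.

    ``gap_policy`` is ``"error"`` (default) or ``"exclude"``: with
    ``"exclude"``, seconds falling in a gap between events are marked with
    the non-wear sentinel (``excluded``) rather than raising.
    """
    if not events:
        raise ValueError("empty event list")
    _validate_event_sequence(events)
    if gap_policy not in ("error", "exclude"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")

    t0 = events[0].start_time
    offsets = np.array(
        [(e.start_time - t0).total_seconds() for e in events], dtype=float
    )
    ends = offsets + np.array([e.duration_s for e in events], dtype=float)
    for k in range(1, len(events)):
        if offsets[k] - ends[k - 1] > _GAP_TOL_S and gap_policy == "error":
            raise ValueError(
                f"gap of {offsets[k] - ends[k - 1]:.3f} s before event {k}; "
                "pass gap_policy='exclude' to fill with the non-wear sentinel"
            )

    n_seconds = int(math.ceil(ends[-1] - _GAP_TOL_S))
    labels = np.zeros(n_seconds, dtype=np.int8)
    excluded = np.ones(n_seconds, dtype=bool)
    midpoints = np.arange(n_seconds) + 0.5
    # second i belongs to the event covering its midpoint
    idx = np.searchsorted(offsets, midpoints, side="right") - 1
    for k, event in enumerate(events):
        mine = (idx == k) & (midpoints < ends[k])
        labels[mine] = _ACTIVITY_TO_CLASS[event.activity]
        excluded[mine] = False

    # transition classes: the first second of the succeeding event at every
    # contiguous sedentary<->upright boundary
    for k in range(1, len(events)):
        if offsets[k] - ends[k - 1] > _GAP_TOL_S:
            continue
        prev_a, cur_a = events[k - 1].activity, events[k].activity
        if prev_a == "sedentary" and cur_a in ("standing", "stepping"):
            trans = PostureClass.SIT_TO_STAND
        elif prev_a in ("standing", "stepping") and cur_a == "sedentary":
            trans = PostureClass.STAND_TO_SIT
        else:
            continue
        first_sec = int(np.ceil(offsets[k] - 0.5))
        if 0 <= first_sec < n_seconds:
            labels[first_sec] = trans
            excluded[first_sec] = False

    return SecondLabelSeries(start_time=t0, labels=labels, excluded=excluded)


def read_epoch_counts(path) -> EpochCountSeries:
    path = Path(path)
    meta, _ = _read_header_comments(path)
    df = pd.read_csv(path, comment="#")
    if "count" not in df.columns:
        raise ParseError(f"{path}: expected a 'count' column")
    counts = pd.to_numeric(df["count"], errors="raise").to_numpy()
    return EpochCountSeries(
        participant_id=meta.get("participant_id", ""),
        start_time=meta.get("start_time", "1970-01-01"),
        counts=counts,
    )


def write_epoch_counts(series: EpochCountSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# participant_id={series.participant_id}\n")
        fh.write(f"# start_time={series.start_time.isoformat()}\n")
        fh.write("count\n")
        np.savetxt(fh, series.counts, fmt="%d")


def write_second_labels(series: SecondLabelSeries, path) -> None:
    df = pd.DataFrame(
        {
            "second": np.arange(len(series)),
            "label": [CLASS_NAMES[v] for v in series.labels],
            "excluded": series.excluded.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# participant_id={series.participant_id}\n")
        fh.write(f"# start_time={series.start_time.isoformat()}\n")
        df.to_csv(fh, index=False)


def read_second_labels(path) -> SecondLabelSeries:
    path = Path(path)
    meta, _ = _read_header_comments(path)
    df = pd.read_csv(path, comment="#")
    name_to_val = {name: i for i, name in enumerate(CLASS_NAMES)}
    try:
        labels = np.array([name_to_val[v] for v in df["label"]], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"{path}: unknown posture label {exc}") from None
    excluded = df["excluded"].to_numpy(dtype=bool) if "excluded" in df else None
    return SecondLabelSeries(
        start_time=meta.get("start_time", "1970-01-01"),
        labels=labels,
        excluded=excluded,
        participant_id=meta.get("participant_id", ""),
    )


def write_posture_sequence(
    labels: np.ndarray,
    path,
    start_time=None,
    window_s: float = 5.0,
    probs: np.ndarray | None = None,
) -> None:
    """Write per-window posture labels (and optionally the five class probabilities)."""
    labels = np.asarray(labels)
    start_time = pd.Timestamp(start_time) if start_time is not None else pd.Timestamp(0)
    starts = [
        (start_time + pd.Timedelta(seconds=i * window_s)).isoformat()
        for i in range(len(labels))
    ]
    df = pd.DataFrame({"window_start": starts, "label": [CLASS_NAMES[v] for v in labels]})
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (len(labels), 5):
            raise ValueError("probs must be (n_windows, 5)")
        for j, name in enumerate(CLASS_NAMES):
            df[f"p_{name.lower()}"] = probs[:, j]
    df.to_csv(path, index=False, float_format="%.6f")


def read_posture_sequence(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a posture-sequence file; returns (labels, probs-or-None)."""
    df = pd.read_csv(path, comment="#")
    name_to_val = {name: i for i, name in enumerate(CLASS_NAMES)}
    labels = np.array([name_to_val[v] for v in df["label"]], dtype=np.int8)
    prob_cols = [f"p_{name.lower()}" for name in CLASS_NAMES]
    probs = None
    if all(c in df.columns for c in prob_cols):
        probs = df[prob_cols].to_numpy(dtype=float)
    return labels, probs
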