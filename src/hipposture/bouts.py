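"""Sitting-bout analytics: wear-time masking, the counts-per-minute cut
point, bout segmentation, duration binning and day-level summaries.

Three posture streams feed the same bout machinery for method comparison:

* the thigh-inclinometer ground truth at 1-s resolution,
* the machine-learned 5-s posture sequence,
* the 100-cpm vertical-axis cut point at 1-min resolution.

Non-wear is flagged with the standard 90-minute zero-count rule: a run of at
least 90 consecutive zero-count minutes is non-wear, where interruptions of
at most 2 consecutive non-zero minutes are tolerated provided each
interruption is flanked by at least 30 minutes of zeros on both sides.

A sitting bout is a maximal run of sitting epochs; a sit-to-stand transition
is counted at each bout followed by a non-sitting wear epoch (a bout
truncated by end-of-wear contributes no transition).  Bout durations are
binned half-open into <2, 2-5, 5-10, 10-20, 20-30, 30-60, 60-90 minutes plus
an overflow bin for bouts of 90 minutes or longer, so that per-bin minutes
always sum to total sitting minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EpochCountSeries, SecondLabelSeries

__all__ = [
    "BIN_EDGES_MIN",
    "BIN_LABELS",
    "WearMask",
    "SittingBout",
    "DayBoutSummary",
    "choi_wear_mask",
    "cutpoint_sedentary",
    "detect_bouts",
    "bin_and_summarize",
    "match_weartime",
    "day_average",
    "summary_table",
]

BIN_EDGES_MIN: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 20.0, 30.0, 60.0, 90.0, np.inf)
BIN_LABELS: tuple[str, ...] = ("<2", "2-5", "5-10", "10-20", "20-30", "30-60", "60-90", "90+")


@dataclass
class WearMask:
    """Per-minute wear flags (True = worn), aligned to an epoch count series."""

    start_time: pd.Timestamp
    wear: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.wear = np.asarray(self.wear, dtype=bool)

    def __len__(self) -> int:
        return len(self.wear)


@dataclass(frozen=True)
class SittingBout:
    start_time: pd.Timestamp | None
    duration_min: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.duration_min > 0:
            raise ValueError("bout duration must be positive")


def choi_wear_mask(
    counts: EpochCountSeries,
    window_min: int = 90,
    tolerance_min: int = 2,
    flank_min: int = 30,
) -> WearMask:
    """Flag non-wear minutes with the 90-minute zero-count rule.

    Implemented over the run-length encoding of the count series: starting
    from a zero run, following (non-zero, zero) run pairs are absorbed while
    the non-zero interruption is at most ``tolerance_min`` minutes long and
    both adjacent zero runs are at least ``flank_min`` minutes; a chain
    whose total length reaches ``window_min`` is non-wear.
    """
    c = counts.counts
    n = len(c)
    wear = np.ones(n, dtype=bool)

    # run-length encode: list of (is_zero, start, length)
    runs: list[tuple[bool, int, int]] = []
    i = 0
    while i < n:
        j = i
        zero = c[i] == 0
        while j < n and (c[j] == 0) == zero:
            j += 1
        runs.append((zero, i, j - i))
        i = j

    r = 0
    while r < len(runs):
        zero, start, length = runs[r]
        if not zero:
            r += 1
            continue
        # grow a chain of zero runs joined by tolerable interruptions
        last = r
        total = length
        while (
            last + 2 < len(runs)
            and runs[last + 1][2] <= tolerance_min
            and runs[last][2] >= flank_min
            and runs[last + 2][2] >= flank_min
        ):
            total += runs[last + 1][2] + runs[last + 2][2]
            last += 2
        if total >= window_min:
            block_start = runs[r][1]
            block_end = runs[last][1] + runs[last][2]
            wear[block_start:block_end] = False
        r = last + 1
    return WearMask(start_time=counts.start_time, wear=wear)


def cutpoint_sedentary(
    counts: EpochCountSeries,
    mask: WearMask,
    threshold: int = 100,
) -> pd.arrays.BooleanArray:
    """Per-minute sedentary flags under the vertical-axis cut point.

    A wear minute is sedentary iff its count is strictly below ``threshold``
    (100 cpm by default).  Non-wear minutes are neither sedentary nor active
    and come back as missing (NA).
    """
    if len(mask) != len(counts):
        raise ValueError("wear mask not aligned with count series")
    sed = counts.counts < threshold
    return pd.array(np.where(mask.wear, sed, None), dtype="boolean")


def detect_bouts(
    states,
    epoch_s: float,
    valid: np.ndarray | None = None,
    start_time=None,
    source: str = "",
) -> tuple[list[SittingBout], int]:
    """Segment a sitting-indicator stream into bouts and count transitions.

    ``states`` is a per-epoch boolean sitting indicator (a pandas nullable
    boolean array is accepted; NA epochs are treated as invalid/non-wear).
    Bouts are maximal runs of sitting epochs within valid spans; a bout
    never spans invalid epochs.  A sit-to-stand transition is counted for
    each bout immediately followed by a valid non-sitting epoch.
    """
    if isinstance(states, pd.arrays.BooleanArray):
        na = np.asarray(states.isna())
        arr = states.fillna(False).to_numpy(dtype=bool)
        v = ~na if valid is None else np.asarray(valid, bool) & ~na
    else:
        arr = np.asarray(states, dtype=bool)
        v = np.ones(arr.size, dtype=bool) if valid is None else np.asarray(valid, bool)
    if arr.size != v.size:
        raise ValueError("valid mask must align with states")

    start_time = pd.Timestamp(start_time) if start_time is not None else None
    bouts: list[SittingBout] = []
    transitions = 0
    n = arr.size
    i = 0
    while i < n:
        if v[i] and arr[i]:
            j = i
            while j < n and v[j] and arr[j]:
                j += 1
            t0 = (
                start_time + pd.Timedelta(seconds=i * epoch_s)
                if start_time is not None
                else None
            )
            bouts.append(
                SittingBout(
                    start_time=t0,
                    duration_min=(j - i) * epoch_s / 60.0,
                    source=source,
                )
            )
            if j < n and v[j] and not arr[j]:
                transitions += 1
            i = j
        else:
            i += 1
    return bouts, transitions


@dataclass
class DayBoutSummary:
    """Per-day bout counts and minutes in fixed duration bins, for one method."""

    participant_id: str
    date: object
    method: str
    bin_counts: np.ndarray
    bin_minutes: np.ndarray
    total_sitting_min: float
    sit_to_stand_transitions: int
    wear_min: float

    def __post_init__(self) -> None:
        self.bin_counts = np.asarray(self.bin_counts, dtype=np.int64)
        self.bin_minutes = np.asarray(self.bin_minutes, dtype=float)
        if self.bin_counts.size != len(BIN_LABELS) or self.bin_minutes.size != len(
            BIN_LABELS
        ):
            raise ValueError("need one entry per duration bin")
        if abs(self.bin_minutes.sum() - self.total_sitting_min) > 1e-6:
            raise ValueError("per-bin minutes must sum to total sitting minutes")


def bin_and_summarize(
    bouts: list[SittingBout],
    day,
    wear_min: float,
    participant_id: str = "",
    method: str = "",
    transitions: int = 0,
) -> DayBoutSummary:
    """Bin bout durations into the fixed half-open bins and summarise the day."""
    durations = np.array([b.duration_min for b in bouts], dtype=float)
    if np.any(durations <= 0):
        raise ValueError("bout durations must be positive")
    edges = np.asarray(BIN_EDGES_MIN)
    counts = np.zeros(len(BIN_LABELS), dtype=np.int64)
    minutes = np.zeros(len(BIN_LABELS))
    if durations.size:
        idx = np.digitize(durations, edges[1:-1], right=False)  # half-open left-closed
        for k in range(len(BIN_LABELS)):
            sel = idx == k
            counts[k] = int(sel.sum())
            minutes[k] = durations[sel].sum()
    return DayBoutSummary(
        participant_id=participant_id,
        date=day,
        method=method,
        bin_counts=counts,
        bin_minutes=minutes,
        total_sitting_min=float(durations.sum()),
        sit_to_stand_transitions=int(transitions),
        wear_min=float(wear_min),
    )


def match_weartime(seconds: SecondLabelSeries, mask: WearMask) -> SecondLabelSeries:
    """Exclude ground-truth seconds that fall in accelerometer non-wear minutes.

    Aligns the second series to the wear mask by start time; seconds before
    the mask, after its end, or inside non-wear minutes are marked excluded
    so that a standard wear time is compared across devices.
    """
    offset_s = (seconds.start_time - mask.start_time).total_seconds()
    n_sec = len(seconds)
    mask_span_s = len(mask) * 60.0
    if offset_s + n_sec <= 0 or offset_s >= mask_span_s:
        raise ValueError("label series and wear mask do not overlap in time")

    sec_minutes = np.floor((np.arange(n_sec) + offset_s) / 60.0).astype(np.int64)
    inside = (sec_minutes >= 0) & (sec_minutes < len(mask))
    worn = np.zeros(n_sec, dtype=bool)
    worn[inside] = mask.wear[sec_minutes[inside]]
    return SecondLabelSeries(
        start_time=seconds.start_time,
        labels=seconds.labels.copy(),
        excluded=seconds.excluded | ~worn,
        participant_id=seconds.participant_id,
    )


def summary_table(summaries: list[DayBoutSummary]) -> pd.DataFrame:
    """Long-format day-level comparison table (one row per day, method, bin)."""
    rows = []
    for s in summaries:
        for k, label in enumerate(BIN_LABELS):
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "date": s.date,
                    "method": s.method,
                    "bin": label,
                    "bout_count": int(s.bin_counts[k]),
                    "bout_minutes": float(s.bin_minutes[k]),
                    "total_sitting_min": s.total_sitting_min,
                    "transitions": s.sit_to_stand_transitions,
                    "wear_min": s.wear_min,
                }
            )
    return pd.DataFrame(rows)


def day_average(summaries: list[DayBoutSummary]) -> pd.DataFrame:
    """Unweighted per-participant, per-method mean over days.

    Returns one row per participant and method with per-bin mean counts and
    minutes plus mean totals — the shape consumed by day-level model fits.
    """
    if not summaries:
        raise ValueError("no summaries")
    table = summary_table(summaries)
    wide = table.pivot_table(
        index=["participant_id", "method", "date"],
        columns="bin",
        values=["bout_count", "bout_minutes"],
        aggfunc="sum",
    )
    per_day_totals = table.groupby(["participant_id", "method", "date"]).agg(
        total_sitting_min=("total_sitting_min", "first"),
        transitions=("transitions", "first"),
        wear_min=("wear_min", "first"),
    )
    wide.columns = ["_".join(c) for c in wide.columns]
    joined = wide.join(per_day_totals)
    out = joined.groupby(level=["participant_id", "method"]).mean()
    return out.reset_index()
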