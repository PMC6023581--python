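"""End-to-end orchestration: cohort -> features -> LOPO -> bouts comparison.

These helpers tie the modules together for the CLI and for scripted
experiments.  The method-comparison path produces, for each participant-day,
a bout summary per method (ground truth, machine-learned, cut point) over a
common accelerometer wear time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bouts import (
    DayBoutSummary,
    WearMask,
    bin_and_summarize,
    choi_wear_mask,
    cutpoint_sedentary,
    detect_bouts,
    match_weartime,
    summary_table,
)
from .classifier import (
    ForestConfig,
    LopoResult,
    ParticipantWindows,
    lopo_cross_validate,
    window_labels_from_seconds,
)
from .core import PostureClass
from .features import feature_matrix
from .synthetic import ParticipantBundle

__all__ = [
    "PipelineConfig",
    "build_participant_windows",
    "run_lopo",
    "compare_methods",
]

METHOD_TRUTH = "activpal"
METHOD_ML = "machine_learned"
METHOD_CUTPOINT = "cutpoint"


@dataclass
class PipelineConfig:
    """Resolved configuration for a pipeline run; defaults are the method constants."""

    window_s: float = 5.0
    lowpass_cutoff_hz: float = 0.5
    n_trees: int = 500
    feature_fraction: float = 0.15
    cutpoint_threshold: int = 100
    choi_window_min: int = 90
    choi_tolerance_min: int = 2
    choi_flank_min: int = 30
    seed: int = 0

    def forest_config(self) -> ForestConfig:
        return ForestConfig(
            n_trees=self.n_trees,
            feature_fraction=self.feature_fraction,
            seed=self.seed,
        )


def build_participant_windows(
    bundle: ParticipantBundle, config: PipelineConfig | None = None
) -> ParticipantWindows:
    """Features + ground-truth window labels for one participant."""
    config = config or PipelineConfig()
    feats = feature_matrix(
        bundle.recording,
        window_s=config.window_s,
        lowpass_cutoff_hz=config.lowpass_cutoff_hz,
    )
    labels, pure = window_labels_from_seconds(
        bundle.truth, len(feats), window_s=config.window_s
    )
    return ParticipantWindows(
        participant_id=bundle.participant_id,
        features=feats,
        labels=labels,
        pure=pure,
    )


def run_lopo(
    bundles: list[ParticipantBundle], config: PipelineConfig | None = None
) -> tuple[LopoResult, list[ParticipantWindows]]:
    """Feature-extract the whole cohort and run leave-one-participant-out CV."""
    config = config or PipelineConfig()
    cohort = [build_participant_windows(b, config) for b in bundles]
    result = lopo_cross_validate(cohort, config.forest_config())
    return result, cohort


def _windows_wear_mask(mask: WearMask, n_windows: int, window_s: float) -> np.ndarray:
    """True for 5-s windows lying entirely inside wear minutes."""
    wear_seconds = np.repeat(mask.wear, 60)
    w = int(round(window_s))
    out = np.zeros(n_windows, dtype=bool)
    for i in range(n_windows):
        lo, hi = i * w, (i + 1) * w
        if hi <= wear_seconds.size and np.all(wear_seconds[lo:hi]):
            out[i] = True
    return out


def compare_methods(
    bundles: list[ParticipantBundle],
    config: PipelineConfig | None = None,
    lopo: LopoResult | None = None,
) -> tuple[pd.DataFrame, list[DayBoutSummary]]:
    """Day-level bout comparison across the three sitting estimates.

    For each participant-day the accelerometer wear mask (zero-count rule)
    defines a common wear time; the ground-truth seconds, the machine-learned
    5-s posture sequence and the cut-point minutes are each segmented into
    sitting bouts, binned, and summarised.  Returns the long-format table and
    the underlying summaries.
    """
    config = config or PipelineConfig()
    if lopo is None:
        lopo, _ = run_lopo(bundles, config)

    summaries: list[DayBoutSummary] = []
    for b in bundles:
        mask = choi_wear_mask(
            b.counts,
            window_min=config.choi_window_min,
            tolerance_min=config.choi_tolerance_min,
            flank_min=config.choi_flank_min,
        )
        wear_min = float(mask.wear.sum())
        day = b.truth.start_time.date()

        # ground truth at 1-s resolution, restricted to accelerometer wear
        truth_matched = match_weartime(b.truth, mask)
        t_bouts, t_trans = detect_bouts(
            truth_matched.labels == int(PostureClass.SIT),
            epoch_s=1.0,
            valid=~truth_matched.excluded,
            start_time=truth_matched.start_time,
            source=METHOD_TRUTH,
        )
        summaries.append(
            bin_and_summarize(
                t_bouts, day, wear_min, b.participant_id, METHOD_TRUTH, t_trans
            )
        )

        # machine-learned 5-s posture sequence
        fold = lopo.folds[b.participant_id]
        valid_w = _windows_wear_mask(mask, len(fold.predicted), config.window_s)
        m_bouts, m_trans = detect_bouts(
            fold.predicted == int(PostureClass.SIT),
            epoch_s=config.window_s,
            valid=valid_w,
            start_time=b.truth.start_time,
            source=METHOD_ML,
        )
        summaries.append(
            bin_and_summarize(
                m_bouts, day, wear_min, b.participant_id, METHOD_ML, m_trans
            )
        )

        # cut point at 1-min resolution
        sed = cutpoint_sedentary(b.counts, mask, threshold=config.cutpoint_threshold)
        c_bouts, c_trans = detect_bouts(
            sed,
            epoch_s=60.0,
            start_time=b.counts.start_time,
            source=METHOD_CUTPOINT,
        )
        summaries.append(
            bin_and_summarize(
                c_bouts, day, wear_min, b.participant_id, METHOD_CUTPOINT, c_trans
            )
        )

    return summary_table(summaries), summaries
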