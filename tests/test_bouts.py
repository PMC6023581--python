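"""Wear-time masking, cut point, bout segmentation, binning, day summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipposture.bouts import (
    BIN_LABELS,
    SittingBout,
    WearMask,
    bin_and_summarize,
    choi_wear_mask,
    cutpoint_sedentary,
    day_average,
    detect_bouts,
    match_weartime,
    summary_table,
)
from hipposture.core import EpochCountSeries, SecondLabelSeries

from _oracles import bout_oracle, choi_oracle

T0 = pd.Timestamp("2024-03-04T08:00:00")
SIT, STAND, STEP, S2S, ST2S = range(5)


def counts(values):
    return EpochCountSeries("P", T0, np.asarray(values))


class TestChoiWearMask:
    def test_long_zero_run_is_nonwear(self):
        mask = choi_wear_mask(counts([0] * 120 + [500] * 60))
        assert not mask.wear[:120].any()
        assert mask.wear[120:].all()

    def test_flanked_spike_absorbed(self):
        # 59 zeros, one spike, 60 zeros: a 120-min block with a tolerable interruption
        mask = choi_wear_mask(counts([0] * 59 + [300] + [0] * 60))
        assert not mask.wear.any()

    def test_all_active_is_wear(self):
        mask = choi_wear_mask(counts([200] * 100))
        assert mask.wear.all()

    def test_short_zero_run_is_wear(self):
        mask = choi_wear_mask(counts([0] * 89 + [300] * 30))
        assert mask.wear.all()

    def test_unflanked_spike_breaks_run(self):
        # spike with only 20 zeros before it is not a valid interruption, so
        # the zero runs stay separate (20 and 80 min, both under 90): all wear
        mask = choi_wear_mask(counts([0] * 20 + [300] + [0] * 80 + [300] * 10))
        assert mask.wear.all()
        # with a 30-min left flank the same spike is absorbed: 111 min non-wear
        mask2 = choi_wear_mask(counts([0] * 30 + [300] + [0] * 80 + [300] * 10))
        assert not mask2.wear[:111].any()
        assert mask2.wear[111:].all()

    def test_matches_brute_force_on_random_series(self, rng):
        """Greedy run-chain equals block enumeration on 50 random 1000-min series."""
        for _ in range(50):
            # sparse nonzero minutes so long zero runs actually occur
            c = np.where(rng.random(1000) < 0.03, rng.integers(1, 500, 1000), 0)
            got = choi_wear_mask(counts(c)).wear
            want = choi_oracle(c)
            np.testing.assert_array_equal(got, want)


class TestCutpoint:
    def test_strict_threshold(self):
        mask = WearMask(T0, np.ones(5, bool))
        sed = cutpoint_sedentary(counts([0, 50, 99, 100, 101]), mask)
        assert list(sed) == [True, True, True, False, False]

    def test_nonwear_is_neither(self):
        mask = WearMask(T0, np.array([False, True]))
        sed = cutpoint_sedentary(counts([99, 99]), mask)
        assert pd.isna(sed[0]) and sed[1] is np.True_ or sed[1] == True  # noqa: E712

    def test_custom_threshold(self):
        mask = WearMask(T0, np.ones(3, bool))
        sed = cutpoint_sedentary(counts([99, 150, 250]), mask, threshold=200)
        assert list(sed) == [True, True, False]

    def test_misaligned_mask_rejected(self):
        with pytest.raises(ValueError):
            cutpoint_sedentary(counts([0, 0]), WearMask(T0, np.ones(3, bool)))


class TestDetectBouts:
    def test_minute_stream_truncated_tail(self):
        flags = [True] * 3 + [False] * 2 + [True] * 10
        bouts, trans = detect_bouts(flags, epoch_s=60.0)
        assert [b.duration_min for b in bouts] == [3.0, 10.0]
        assert trans == 1  # trailing bout truncated by end of stream

    def test_all_sitting_no_transitions(self):
        bouts, trans = detect_bouts([True] * 60, epoch_s=60.0)
        assert len(bouts) == 1 and bouts[0].duration_min == 60.0
        assert trans == 0

    def test_five_second_stream_with_transition_window(self):
        labels = np.array([SIT] * 24 + [S2S] + [STAND] * 12)
        bouts, trans = detect_bouts(labels == SIT, epoch_s=5.0)
        assert len(bouts) == 1
        assert bouts[0].duration_min == pytest.approx(2.0)
        assert trans == 1

    def test_empty_input(self):
        bouts, trans = detect_bouts(np.array([], dtype=bool), epoch_s=60.0)
        assert bouts == [] and trans == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_run_length_oracle(self, seed):
        r = np.random.default_rng(seed)
        sitting = r.random(120) < 0.6
        valid = r.random(120) < 0.9
        bouts, trans = detect_bouts(sitting, epoch_s=60.0, valid=valid)
        want_durations, want_trans = bout_oracle(sitting, valid, 60.0)
        assert [b.duration_min for b in bouts] == want_durations
        assert trans == want_trans


class TestBinning:
    def test_binning_arithmetic(self):
        bouts = [SittingBout(None, d) for d in (1.5, 3.0, 25.0, 75.0)]
        s = bin_and_summarize(bouts, T0.date(), wear_min=480)
        np.testing.assert_array_equal(s.bin_counts, [1, 1, 0, 0, 1, 0, 1, 0])
        np.testing.assert_allclose(s.bin_minutes, [1.5, 3, 0, 0, 25, 0, 75, 0])
        assert s.total_sitting_min == pytest.approx(104.5)

    def test_half_open_edges(self):
        s = bin_and_summarize([SittingBout(None, 2.0)], T0.date(), 480)
        assert s.bin_counts[1] == 1 and s.bin_counts[0] == 0
        s90 = bin_and_summarize([SittingBout(None, 90.0)], T0.date(), 480)
        assert s90.bin_counts[-1] == 1

    def test_empty_day(self):
        s = bin_and_summarize([], T0.date(), 480)
        assert s.bin_counts.sum() == 0 and s.total_sitting_min == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_conservation(self, seed):
        r = np.random.default_rng(seed)
        durations = r.lognormal(1.5, 1.2, size=r.integers(1, 40))
        bouts = [SittingBout(None, d) for d in durations]
        s = bin_and_summarize(bouts, T0.date(), 480)
        assert s.bin_minutes.sum() == pytest.approx(s.total_sitting_min, abs=1e-6)
        assert s.bin_counts.sum() == len(bouts)


class TestMatchWeartime:
    def test_all_wear_unchanged(self):
        series = SecondLabelSeries(T0, np.full(600, SIT))
        mask = WearMask(T0, np.ones(10, bool))
        out = match_weartime(series, mask)
        assert not out.excluded.any()

    def test_leading_nonwear_excluded(self):
        series = SecondLabelSeries(T0, np.full(7200, SIT))
        wear = np.ones(120, bool)
        wear[:90] = False
        out = match_weartime(series, WearMask(T0, wear))
        assert out.excluded[:5400].all()
        assert not out.excluded[5400:].any()

    def test_disjoint_spans_rejected(self):
        series = SecondLabelSeries(T0, np.full(60, SIT))
        mask = WearMask(T0 + pd.Timedelta(hours=12), np.ones(10, bool))
        with pytest.raises(ValueError):
            match_weartime(series, mask)

    def test_no_bout_spans_excluded_gap(self, rng):
        """Bouts detected after wear matching never cross a non-wear minute."""
        for _ in range(10):
            n_min = 30
            labels = np.full(n_min * 60, SIT)
            wear = rng.random(n_min) < 0.7
            series = SecondLabelSeries(T0, labels)
            out = match_weartime(series, WearMask(T0, wear))
            bouts, _ = detect_bouts(
                out.labels == SIT, epoch_s=1.0, valid=~out.excluded
            )
            want, _ = bout_oracle(out.labels == SIT, ~out.excluded, 1.0)
            assert [b.duration_min for b in bouts] == want
            # each bout fits inside one maximal wear run
            wear_runs = np.flatnonzero(np.diff(np.r_[0, wear.view(np.int8), 0]))
            max_run = max(
                (b - a for a, b in zip(wear_runs[::2], wear_runs[1::2])), default=0
            )
            assert all(b.duration_min <= max_run for b in bouts)


class TestDaySummaries:
    def _summary(self, pid, day, total):
        return bin_and_summarize(
            [SittingBout(None, total)], day, 480, participant_id=pid, method="activpal"
        )

    def test_identical_days_average(self):
        s = self._summary("A", T0.date(), 30.0)
        out = day_average([s, s])
        assert out.loc[0, "total_sitting_min"] == pytest.approx(30.0)

    def test_mean_of_two_days(self):
        a = self._summary("A", T0.date(), 400.0)
        b = self._summary("A", (T0 + pd.Timedelta(days=1)).date(), 500.0)
        out = day_average([a, b])
        assert out.loc[0, "total_sitting_min"] == pytest.approx(450.0)

    def test_table_shape(self):
        summaries = [
            self._summary(pid, T0.date(), 20.0) for pid in ("A", "B", "C")
        ]
        table = summary_table(summaries)
        assert len(table) == 3 * len(BIN_LABELS)
        assert set(table.columns) >= {
            "participant_id", "date", "method", "bin", "bout_count",
            "bout_minutes", "total_sitting_min", "transitions", "wear_min",
        }
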