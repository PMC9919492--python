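"""Bout detection, participant exclusion and hourly states vs oracles."""

import numpy as np
import pandas as pd
import pytest

from walkcast.preprocess import (
    HourState,
    WalkBout,
    cohort_hourly_states,
    detect_bouts,
    exclude_short_participants,
    hourly_states,
    read_states_csv,
    write_states_csv,
)
from walkcast.synthetic import MinuteStepSeries, load_preset, simulate_cohort

from conftest import T0, make_series, random_series, run_series


def bruteforce_bouts(series, min_spm=60, min_len=5):
    """Test every (start, length) pair for the >=spm / >=len / maximality rules."""
    idx = series.steps.index
    minutes = idx.asi8 // 60_000_000_000
    steps = series.steps.to_numpy()
    by_minute = dict(zip(minutes, steps))
    found = []
    for s in minutes:
        if by_minute.get(s, 0) < min_spm or by_minute.get(s - 1, 0) >= min_spm:
            continue  # not a maximal run start
        length = 0
        while by_minute.get(s + length, 0) >= min_spm:
            length += 1
        if length >= min_len:
            found.append((s, length))
    return found


def as_pairs(bouts):
    return [(b.start.value // 60_000_000_000, b.duration_min) for b in bouts]


class TestDetectBouts:
    def test_minimal_qualifying_run(self):
        series = run_series(T0, [70, 80, 90, 100, 110])
        bouts = detect_bouts(series)
        assert len(bouts) == 1
        assert bouts[0].start == T0 and bouts[0].duration_min == 5

    def test_below_length_threshold(self):
        assert detect_bouts(run_series(T0, [70, 80, 90, 100])) == []

    def test_slow_minute_breaks_run(self):
        series = run_series(T0, [70, 80, 59, 90, 100, 110, 120, 130])
        bouts = detect_bouts(series)
        assert len(bouts) == 1
        assert bouts[0].start == T0 + pd.Timedelta(minutes=3)
        assert bouts[0].duration_min == 5

    def test_recording_gap_breaks_run(self):
        """An unrecorded minute splits an otherwise continuous fast run."""
        steps = {f"2015-08-03 09:{m:02d}": 90 for m in (0, 1, 2, 3, 5, 6, 7, 8)}
        assert detect_bouts(make_series(steps)) == []

    def test_empty_series(self):
        empty = MinuteStepSeries("P0", pd.Series([], index=pd.DatetimeIndex([]), dtype=np.int64))
        assert detect_bouts(empty) == []

    def test_matches_bruteforce_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(1000):
            series = random_series(rng)
            assert as_pairs(detect_bouts(series)) == bruteforce_bouts(series)
            checked += 1
        assert checked == 1000

    def test_threshold_monotonicity(self):
        """Raising min_spm or min_len never increases the bout count."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            series = random_series(rng)
            base = len(detect_bouts(series, min_spm=60, min_len=5))
            assert len(detect_bouts(series, min_spm=80, min_len=5)) <= base
            assert len(detect_bouts(series, min_spm=60, min_len=7)) <= base


class TestExclusion:
    def _series_with_days(self, n_days, pid):
        steps = {f"2015-08-{3+d:02d} 10:00": 50 for d in range(n_days)}
        return make_series(steps, pid=pid)

    def test_boundary_below_threshold_excluded(self):
        cohort = [self._series_with_days(9, "P9"), self._series_with_days(10, "P10")]
        retained, excluded = exclude_short_participants(cohort, min_days=10)
        assert [s.participant_id for s in retained] == ["P10"]
        assert excluded == ["P9"]

    def test_all_missing_participants_dropped(self):
        cfg = load_preset(
            "default", n_participants=5, n_days=15, seed=2
        ).replace(missing_day_prob=0.1)
        cohort = simulate_cohort(cfg)
        for i in (1, 3):  # overwrite two streams with empty ones
            cohort[i] = MinuteStepSeries(
                cohort[i].participant_id,
                pd.Series([], index=pd.DatetimeIndex([]), dtype=np.int64),
            )
        retained, excluded = exclude_short_participants(cohort)
        assert len(retained) == 3 and len(excluded) == 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            exclude_short_participants([])


class TestHourlyStates:
    def test_boundary_spanning_bout_marks_both_hours(self):
        steps = {f"2015-08-03 13:5{m}": 90 for m in range(7, 10)}
        steps |= {f"2015-08-03 14:0{m}": 90 for m in range(0, 7)}
        series = make_series(steps)
        states = hourly_states(series, detect_bouts(series))
        assert states[pd.Timestamp("2015-08-03 13:00")] == HourState.ACTIVE
        assert states[pd.Timestamp("2015-08-03 14:00")] == HourState.ACTIVE
        assert states[pd.Timestamp("2015-08-03 12:00")] == HourState.INACTIVE

    def test_recorded_day_without_bouts_all_inactive(self):
        steps = {f"2015-08-03 08:{m:02d}": 30 for m in range(20)}
        series = make_series(steps)
        states = hourly_states(series, [])
        assert len(states) == 24
        assert (states.to_numpy() == HourState.INACTIVE).all()

    def test_unrecorded_day_inside_span_is_missing(self):
        steps = {"2015-08-03 08:00": 10, "2015-08-05 08:00": 10}
        series = make_series(steps)
        states = hourly_states(series, [])
        day2 = states[states.index.normalize() == pd.Timestamp("2015-08-04")]
        assert len(day2) == 24
        assert (day2.to_numpy() == HourState.MISSING).all()

    def test_span_partition_counts(self):
        """ACTIVE + INACTIVE + MISSING = 24 x span days, for simulated data."""
        cfg = load_preset("default", n_participants=4, n_days=15, seed=9)
        for pid, states in cohort_hourly_states(simulate_cohort(cfg)).items():
            assert len(states) % 24 == 0
            span_days = len(states) // 24
            codes = states.to_numpy()
            total = sum(
                int((codes == s).sum())
                for s in (HourState.ACTIVE, HourState.INACTIVE, HourState.MISSING)
            )
            assert total == 24 * span_days

    def test_every_active_hour_intersects_a_bout(self):
        cfg = load_preset("default", n_participants=3, n_days=15, seed=4)
        for series in simulate_cohort(cfg):
            bouts = detect_bouts(series)
            states = hourly_states(series, bouts)
            active_hours = set(states.index[states.to_numpy() == HourState.ACTIVE])
            bout_hours = set()
            for b in bouts:
                h = b.start.floor("h")
                while h < b.end:
                    bout_hours.add(h)
                    h += pd.Timedelta(hours=1)
            assert active_hours == bout_hours

    def test_inconsistent_bouts_rejected(self):
        series = run_series(T0, [70, 80, 90, 100, 110])
        alien = WalkBout("P000", T0 + pd.Timedelta(hours=5), 5)
        with pytest.raises(ValueError, match="absent from the series"):
            hourly_states(series, [alien])

    def test_states_csv_round_trip(self, tmp_path):
        cfg = load_preset("default", n_participants=2, n_days=8, seed=1)
        states = cohort_hourly_states(simulate_cohort(cfg))
        write_states_csv(states, tmp_path / "states.csv")
        back = read_states_csv(tmp_path / "states.csv")
        assert set(back) == set(states)
        for pid in states:
            pd.testing.assert_series_equal(
                states[pid], back[pid], check_names=False, check_freq=False
            )
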