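"""Shared fixtures: hand-built minute series and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from walkcast.preprocess import cohort_hourly_states
from walkcast.synthetic import MinuteStepSeries, load_preset, simulate_cohort

T0 = pd.Timestamp("2015-08-03 00:00")  # a Monday


def make_series(minute_steps: dict[str, int], pid: str = "P000") -> MinuteStepSeries:
    """Build a series from {"YYYY-mm-dd HH:MM": steps} pairs."""
    idx = pd.DatetimeIndex(sorted(pd.Timestamp(k) for k in minute_steps))
    vals = np.array([minute_steps[str(t)[:16].replace("T", " ")] for t in idx])
    return MinuteStepSeries(participant_id=pid, steps=pd.Series(vals, index=idx))


def run_series(start: pd.Timestamp, steps: list[int], pid: str = "P000") -> MinuteStepSeries:
    """A series of consecutive minutes starting at ``start``."""
    idx = pd.date_range(start, periods=len(steps), freq="min")
    return MinuteStepSeries(
        participant_id=pid, steps=pd.Series(np.asarray(steps), index=idx)
    )


def random_series(rng: np.random.Generator, pid: str = "P000") -> MinuteStepSeries:
    """A short random series with gaps, mixed cadences, and varied run lengths."""
    n = int(rng.integers(1, 120))
    # gaps of 1 minute are frequent so runs break both ways
    gaps = rng.choice([1, 1, 1, 1, 2, 3, 10], size=n)
    minutes = np.cumsum(gaps)
    steps = rng.choice([0, 10, 59, 60, 61, 80, 120], size=n)
    idx = T0 + pd.to_timedelta(minutes, unit="min")
    return MinuteStepSeries(participant_id=pid, steps=pd.Series(steps, index=idx))


@pytest.fixture(scope="session")
def structured_small():
    """A small structured-preset cohort with its hourly states (shared)."""
    cfg = load_preset("structured", n_participants=8, n_days=30, seed=11)
    cohort = simulate_cohort(cfg)
    states = cohort_hourly_states(cohort)
    return cfg, cohort, states


@pytest.fixture(scope="session")
def null_small():
    cfg = load_preset("null", n_participants=6, n_days=25, seed=11)
    cohort = simulate_cohort(cfg)
    states = cohort_hourly_states(cohort)
    return cfg, cohort, states
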