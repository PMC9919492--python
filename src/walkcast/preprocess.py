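"""Exclusion and transformation of minute-level step streams.

Three rules reduce raw streams to hourly walking states:

1. participants with data on fewer than ``min_days`` distinct calendar days
   are excluded;
2. a *walk bout* is a maximal run of consecutive minutes (timestamps exactly
   one minute apart), each with at least ``min_spm`` steps, lasting at least
   ``min_len`` minutes;
3. each clock hour of a participant's span becomes ACTIVE (contains >= 1 bout
   minute), INACTIVE (recorded day, no bout minute) or MISSING (the whole
   calendar day has no records).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import MinuteStepSeries

__all__ = [
    "HourState",
    "WalkBout",
    "exclude_short_participants",
    "detect_bouts",
    "hourly_states",
    "cohort_hourly_states",
    "write_states_csv",
    "read_states_csv",
]


class HourState(IntEnum):
    """State of one participant-hour."""

    INACTIVE = 0
    ACTIVE = 1
    MISSING = 2


@dataclass(frozen=True)
class WalkBout:
    """A maximal run of >= min_len consecutive minutes at >= min_spm steps."""

    participant_id: str
    start: pd.Timestamp
    duration_min: int

    @property
    def end(self) -> pd.Timestamp:
        """First minute after the bout (exclusive)."""
        return self.start + pd.Timedelta(minutes=self.duration_min)


def exclude_short_participants(
    cohort: Iterable[MinuteStepSeries], min_days: int = 10
) -> tuple[list[MinuteStepSeries], list[str]]:
    """Drop participants with data on fewer than ``min_days`` distinct days.

    Returns (retained cohort, excluded participant ids).
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    retained, excluded = [], []
    for series in cohort:
        if len(series.recorded_days) >= min_days:
            retained.append(series)
        else:
            excluded.append(series.participant_id)
    return retained, excluded


def detect_bouts(
    series: MinuteStepSeries, min_spm: int = 60, min_len: int = 5
) -> list[WalkBout]:
    """All maximal qualifying runs, ordered by start time.

    Consecutiveness requires timestamps exactly one minute apart; any gap in
    the record (even an unrecorded minute) breaks a run.
    """
    if len(series) == 0:
        return []
    steps = series.steps.to_numpy()
    minutes = series.steps.index.asi8 // 60_000_000_000  # epoch minutes
    fast = steps >= min_spm
    idx = np.nonzero(fast)[0]
    if idx.size == 0:
        return []
    fast_minutes = minutes[idx]
    # A run breaks where the *minute* gap exceeds 1 (missing or slow minute).
    breaks = np.nonzero(np.diff(fast_minutes) != 1)[0]
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [fast_minutes.size - 1]])
    bouts = []
    for s, e in zip(run_starts, run_ends):
        length = int(fast_minutes[e] - fast_minutes[s]) + 1
        if length >= min_len:
            bouts.append(
                WalkBout(
                    participant_id=series.participant_id,
                    start=series.steps.index[idx[s]],
                    duration_min=length,
                )
            )
    return bouts


def _check_bouts_consistent(
    series: MinuteStepSeries, bouts: Sequence[WalkBout], min_spm: int = 60
) -> None:
    index = series.steps.index
    for bout in bouts:
        rng = pd.date_range(bout.start, periods=bout.duration_min, freq="min")
        pos = index.get_indexer(rng)
        if (pos < 0).any():
            raise ValueError(
                f"bout at {bout.start} references minutes absent from the series"
            )
        if (series.steps.to_numpy()[pos] < min_spm).any():
            raise ValueError(f"bout at {bout.start} covers sub-threshold minutes")


def hourly_states(
    series: MinuteStepSeries, bouts: Sequence[WalkBout]
) -> pd.Series:
    """Hourly ACTIVE/INACTIVE/MISSING states over the participant's span.

    The span runs from the first record's midnight through the last record's
    end of day.  Hours on unrecorded calendar days are MISSING; an hour with
    at least one bout minute is ACTIVE (a bout spanning an hour boundary marks
    both hours); all other hours on recorded days are INACTIVE.  Returns an
    int8 Series of :class:`HourState` codes indexed by hour timestamps.
    """
    if len(series) == 0:
        return pd.Series(
            np.empty(0, dtype=np.int8),
            index=pd.DatetimeIndex([]),
            name=series.participant_id,
        )
    _check_bouts_consistent(series, bouts)
    first_day = series.steps.index[0].normalize()
    last_day = series.steps.index[-1].normalize()
    hours = pd.date_range(
        first_day, last_day + pd.Timedelta(hours=23), freq="h"
    )
    states = np.full(hours.size, HourState.INACTIVE, dtype=np.int8)

    recorded = set(series.recorded_days)
    day_of_hour = hours.normalize()
    missing_mask = np.fromiter(
        (d not in recorded for d in day_of_hour), bool, hours.size
    )
    states[missing_mask] = HourState.MISSING

    for bout in bouts:
        h0 = bout.start.floor("h")
        h1 = (bout.end - pd.Timedelta(minutes=1)).floor("h")
        lo = hours.searchsorted(h0)
        hi = hours.searchsorted(h1, side="right")
        states[lo:hi] = HourState.ACTIVE

    return pd.Series(states, index=hours, name=series.participant_id)


def cohort_hourly_states(
    cohort: Iterable[MinuteStepSeries],
    min_spm: int = 60,
    min_len: int = 5,
) -> dict[str, pd.Series]:
    """Detect bouts and derive hourly states for every participant."""
    out: dict[str, pd.Series] = {}
    for series in cohort:
        bouts = detect_bouts(series, min_spm=min_spm, min_len=min_len)
        out[series.participant_id] = hourly_states(series, bouts)
    return out


def write_states_csv(states: dict[str, pd.Series], path: str | Path) -> None:
    """Write hourly states as delimited text: participant_id,hour,state."""
    rows = []
    for pid, s in states.items():
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "hour": s.index.strftime("%Y-%m-%dT%H:%M"),
                    "state": [HourState(v).name for v in s.to_numpy()],
                }
            )
        )
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["participant_id", "hour", "state"])
    )
    out.to_csv(path, index=False)


def read_states_csv(path: str | Path) -> dict[str, pd.Series]:
    df = pd.read_csv(path, parse_dates=["hour"])
    out: dict[str, pd.Series] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("hour")
        codes = np.array([HourState[s] for s in grp["state"]], dtype=np.int8)
        out[str(pid)] = pd.Series(
            codes, index=pd.DatetimeIndex(grp["hour"]), name=str(pid)
        )
    return out
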