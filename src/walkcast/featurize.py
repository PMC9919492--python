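"""Predictor vectors and outcome labels for participant-hour anchors.

Each instance is anchored at one participant-hour.  Its predictors are a
2,594-long binary vector laid out as

====================  ======  =========================================
block                 width   encoding
====================  ======  =========================================
hour of day           24      one-hot, 0-23
day of week           7       one-hot, Monday=0
month                 12      one-hot, January=0
day of month          31      one-hot, 1st=0
lag history           2520    840 lag hours x 3-state one-hot
====================  ======  =========================================

Lag ell = 1..840 (the 5 weeks of hours immediately preceding the anchor) maps
to the triple at offset ``74 + (ell-1)*3``; within a triple the positions are
(INACTIVE, ACTIVE, MISSING), i.e. the :class:`~walkcast.preprocess.HourState`
code.  Hours before the participant's span are encoded MISSING, so early
anchors are usable.  Every instance therefore carries exactly 4 + 840 = 844
ones.

The outcome looks *forward*: label 1 if any of the ``horizon`` hours starting
at the anchor is ACTIVE, 0 if none is and at least one is observed, and no
instance at all when every outcome hour is MISSING or the window runs past
the span.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import HourState

__all__ = [
    "N_FEATURES",
    "N_LAGS",
    "TEMPORAL_WIDTH",
    "InstanceSet",
    "encode_time",
    "encode_history",
    "label_outcome",
    "build_instances",
]

HOUR_WIDTH = 24
DOW_WIDTH = 7
MONTH_WIDTH = 12
DOM_WIDTH = 31
TEMPORAL_WIDTH = HOUR_WIDTH + DOW_WIDTH + MONTH_WIDTH + DOM_WIDTH  # 74
N_LAGS = 840  # 5 weeks x 7 days x 24 hours
N_STATES = 3
N_FEATURES = TEMPORAL_WIDTH + N_LAGS * N_STATES  # 2594

SKIP = None  # sentinel returned by label_outcome for non-instances

_EYE3 = np.eye(N_STATES, dtype=np.uint8)


def encode_time(anchor: pd.Timestamp) -> np.ndarray:
    """One-hot temporal block (length 74) for an anchor hour."""
    anchor = pd.Timestamp(anchor)
    vec = np.zeros(TEMPORAL_WIDTH, dtype=np.uint8)
    vec[anchor.hour] = 1
    vec[HOUR_WIDTH + anchor.dayofweek] = 1
    vec[HOUR_WIDTH + DOW_WIDTH + anchor.month - 1] = 1
    vec[HOUR_WIDTH + DOW_WIDTH + MONTH_WIDTH + anchor.day - 1] = 1
    return vec


def _state_codes(states: pd.Series, anchor: pd.Timestamp) -> tuple[np.ndarray, int]:
    """(codes array, anchor position) with basic span checks."""
    anchor = pd.Timestamp(anchor)
    pos = states.index.get_indexer([anchor])[0]
    if pos < 0:
        raise ValueError(f"anchor {anchor} not in the participant's span")
    return states.to_numpy(), int(pos)


def encode_history(states: pd.Series, anchor: pd.Timestamp) -> np.ndarray:
    """One-hot 5-week lag history (length 2520) ending the hour before anchor."""
    codes, pos = _state_codes(states, anchor)
    lags = np.full(N_LAGS, int(HourState.MISSING), dtype=np.int8)
    avail = min(N_LAGS, pos)
    if avail:
        # lag 1 is the hour at pos-1, lag `avail` the hour at pos-avail
        lags[:avail] = codes[pos - avail : pos][::-1]
    return _EYE3[lags].reshape(-1)


def label_outcome(
    states: pd.Series, anchor: pd.Timestamp, horizon: int = 3
) -> int | None:
    """Binary "will walk" label over [anchor, anchor+horizon) or SKIP (None)."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    codes, pos = _state_codes(states, anchor)
    window = codes[pos : pos + horizon]
    if window.size < horizon:
        return SKIP  # outcome window extends past the span
    if (window == HourState.ACTIVE).any():
        return 1
    if (window == HourState.MISSING).all():
        return SKIP
    return 0


@dataclass
class InstanceSet:
    """A matrix of instances plus alignment and provenance metadata."""

    X: np.ndarray  # (n, N_FEATURES) uint8
    y: np.ndarray  # (n,) int8
    participant_ids: np.ndarray  # (n,) str
    anchors: pd.DatetimeIndex  # (n,)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.participant_ids) == len(self.anchors) == n):
            raise ValueError("misaligned instance arrays")
        keys = pd.MultiIndex.from_arrays([self.participant_ids, self.anchors])
        if keys.has_duplicates:
            raise ValueError("duplicate (participant, anchor) pairs")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        pos = int(self.y.sum())
        return len(self) - pos, pos

    def subset(self, indices: np.ndarray, note: str | None = None) -> "InstanceSet":
        prov = dict(self.provenance)
        if note:
            prov.setdefault("history", []).append(note)
        return InstanceSet(
            X=self.X[indices],
            y=self.y[indices],
            participant_ids=self.participant_ids[indices],
            anchors=self.anchors[indices],
            provenance=prov,
        )

    def save(self, path: str | Path) -> None:
        """Dense matrix file (.npz) plus a JSON sidecar with the layout."""
        path = Path(path)
        np.savez_compressed(
            path,
            X=self.X,
            y=self.y,
            participant_ids=self.participant_ids.astype(str),
            anchors=self.anchors.asi8,
        )
        sidecar = {
            "n_instances": len(self),
            "n_features": int(self.X.shape[1]),
            "layout": {
                "hour_of_day": [0, HOUR_WIDTH],
                "day_of_week": [HOUR_WIDTH, HOUR_WIDTH + DOW_WIDTH],
                "month": [31, 43],
                "day_of_month": [43, TEMPORAL_WIDTH],
                "lag_history": [TEMPORAL_WIDTH, N_FEATURES],
                "lag_state_order": ["INACTIVE", "ACTIVE", "MISSING"],
            },
            "provenance": self.provenance,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "InstanceSet":
        path = Path(path)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            X = z["X"]
            y = z["y"]
            pids = z["participant_ids"].astype(str)
            anchors = pd.DatetimeIndex(z["anchors"].view("datetime64[ns]"))
        sidecar_path = path.with_suffix(".json")
        prov = {}
        if sidecar_path.exists():
            with open(sidecar_path) as fh:
                prov = json.load(fh).get("provenance", {})
        return cls(X=X, y=y, participant_ids=pids, anchors=anchors, provenance=prov)


def _participant_instances(
    pid: str, states: pd.Series, horizon: int
) -> tuple[np.ndarray, np.ndarray, pd.DatetimeIndex]:
    codes = states.to_numpy().astype(np.int8)
    hours = states.index
    T = codes.size
    if T < horizon:
        return (
            np.empty((0, N_FEATURES), np.uint8),
            np.empty(0, np.int8),
            pd.DatetimeIndex([]),
        )

    # Outcome per anchor t over codes[t : t+horizon] (vectorized via windows).
    win = np.lib.stride_tricks.sliding_window_view(codes, horizon)
    any_active = (win == HourState.ACTIVE).any(axis=1)
    all_missing = (win == HourState.MISSING).all(axis=1)
    keep = ~all_missing
    t_idx = np.nonzero(keep)[0]
    if t_idx.size == 0:
        return (
            np.empty((0, N_FEATURES), np.uint8),
            np.empty(0, np.int8),
            pd.DatetimeIndex([]),
        )
    labels = any_active[t_idx].astype(np.int8)

    X = np.zeros((t_idx.size, N_FEATURES), dtype=np.uint8)
    kept_hours = hours[t_idx]
    rows = np.arange(t_idx.size)
    X[rows, kept_hours.hour] = 1
    X[rows, HOUR_WIDTH + kept_hours.dayofweek] = 1
    X[rows, HOUR_WIDTH + DOW_WIDTH + kept_hours.month - 1] = 1
    X[rows, HOUR_WIDTH + DOW_WIDTH + MONTH_WIDTH + kept_hours.day - 1] = 1

    # Lag history: pad the span with 840 MISSING hours, slide, then reverse so
    # column ell-1 is lag ell (the hour anchor-ell).
    padded = np.concatenate(
        [np.full(N_LAGS, int(HourState.MISSING), dtype=np.int8), codes]
    )
    hist = np.lib.stride_tricks.sliding_window_view(padded, N_LAGS)[t_idx]
    hist = hist[:, ::-1]
    X[:, TEMPORAL_WIDTH:] = _EYE3[hist].reshape(t_idx.size, N_LAGS * N_STATES)
    return X, labels, kept_hours


def build_instances(
    cohort_states: Mapping[str, pd.Series],
    horizon: int = 3,
) -> InstanceSet:
    """Build all eligible instances from per-participant hourly states.

    Every hour of every participant's span is a candidate anchor; anchors
    whose outcome window extends past the span or is entirely MISSING are
    skipped.
    """
    if not cohort_states:
        raise ValueError("no hourly states supplied")
    xs, ys, pids, anchors = [], [], [], []
    for pid in sorted(cohort_states):
        X, y, hrs = _participant_instances(pid, cohort_states[pid], horizon)
        if len(y) == 0:
            continue
        xs.append(X)
        ys.append(y)
        pids.append(np.full(len(y), pid, dtype=object))
        anchors.append(hrs)
    if not xs:
        return InstanceSet(
            X=np.empty((0, N_FEATURES), np.uint8),
            y=np.empty(0, np.int8),
            participant_ids=np.empty(0, object),
            anchors=pd.DatetimeIndex([]),
            provenance={"horizon": horizon, "n_lags": N_LAGS},
        )
    return InstanceSet(
        X=np.concatenate(xs),
        y=np.concatenate(ys),
        participant_ids=np.concatenate(pids),
        anchors=pd.DatetimeIndex(np.concatenate([a.asi8 for a in anchors]).view("datetime64[ns]")),
        provenance={"horizon": horizon, "n_lags": N_LAGS},
    )
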