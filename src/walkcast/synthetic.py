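"""Synthetic minute-level step-count streams.

Emulates the structure of consumer wrist-band walking data: a circadian /
weekly walk-bout process, sub-bout background activity, and whole-day
missingness (days the device was not worn).  Every downstream stage of the
pipeline — bout detection, hourly states, featurization, evaluation — runs on
these streams exactly as it would on real exports.

The default preset is calibrated so that a simulated cohort reproduces the
summary statistics the pipeline assumes about free-living adults: roughly 2.6
detected walk bouts per recorded day with mean length ~10.3 minutes, ~146
recorded minutes per day, and ~37% of study days wholly missing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "SampleSpec",
    "GeneratorConfig",
    "MinuteStepSeries",
    "CohortSummary",
    "simulate_participant",
    "simulate_cohort",
    "summarize_cohort",
    "load_preset",
    "available_presets",
    "write_cohort_csv",
    "read_cohort_csv",
]

MINUTES_PER_DAY = 1440


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class SampleSpec:
    """A small distribution spec: family name plus parameters.

    Supported families:

    - ``lognormal``: params ``mu``, ``sigma`` (log-scale), optional
      ``low``/``high`` clip bounds; samples rounded to integers.
    - ``normal``: params ``mean``, ``sd``, optional ``low``/``high``; rounded.
    - ``uniform_int``: params ``low``, ``high`` (inclusive).
    - ``constant``: param ``value``.
    """

    family: str
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        p = self.params
        if self.family == "lognormal":
            if p.get("sigma", 1.0) < 0:
                raise ConfigError("lognormal sigma must be >= 0")
        elif self.family == "normal":
            if p.get("sd", 1.0) < 0:
                raise ConfigError("normal sd must be >= 0")
        elif self.family == "uniform_int":
            if p["low"] > p["high"]:
                raise ConfigError("uniform_int low > high")
        elif self.family == "constant":
            if "value" not in p:
                raise ConfigError("constant spec needs 'value'")
        else:
            raise ConfigError(f"unknown distribution family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "lognormal":
            x = rng.lognormal(p["mu"], p["sigma"], size)
        elif self.family == "normal":
            x = rng.normal(p["mean"], p["sd"], size)
        elif self.family == "uniform_int":
            return rng.integers(p["low"], p["high"] + 1, size)
        elif self.family == "constant":
            return np.full(size, p["value"])
        else:  # pragma: no cover - validate() rejects earlier
            raise ConfigError(f"unknown distribution family {self.family!r}")
        x = np.round(x)
        lo, hi = p.get("low"), p.get("high")
        if lo is not None or hi is not None:
            x = np.clip(x, lo, hi)
        return x.astype(np.int64)

    @property
    def support_min(self) -> float:
        p = self.params
        if self.family == "constant":
            return p["value"]
        if self.family == "uniform_int":
            return p["low"]
        lo = p.get("low")
        return -np.inf if lo is None else lo

    @property
    def support_max(self) -> float:
        p = self.params
        if self.family == "constant":
            return p["value"]
        if self.family == "uniform_int":
            return p["high"]
        hi = p.get("high")
        return np.inf if hi is None else hi


def _default_bout_duration() -> SampleSpec:
    # Calibrated so that, after the 5-minute floor, mean duration ~= 10.3 min.
    return SampleSpec("lognormal", {"mu": 2.09, "sigma": 0.62, "low": 5, "high": 120})


def _default_active_cadence() -> SampleSpec:
    return SampleSpec("normal", {"mean": 100.0, "sd": 15.0, "low": 60, "high": 180})


def _default_background_cadence() -> SampleSpec:
    # Sub-threshold activity: 0-59 steps in a recorded non-bout minute.
    return SampleSpec("lognormal", {"mu": 2.6, "sigma": 0.9, "low": 0, "high": 59})


def _default_background_minutes() -> SampleSpec:
    # Non-bout recorded minutes/day; with ~27 bout min/day this lands total
    # recorded time near 146 min/day.
    return SampleSpec("normal", {"mean": 119.0, "sd": 30.0, "low": 0, "high": 600})


def _default_rate() -> np.ndarray:
    return build_rate_matrix(
        daily_bouts=2.72,
        hourly_weights=_DAYTIME_PROFILE,
        dow_weights=[1.0] * 7,
    )


# Typical commuter/leisure profile: morning, lunch and evening peaks, quiet
# nights.  Only the shape matters; build_rate_matrix rescales it.
_DAYTIME_PROFILE = [
    0.0, 0.0, 0.0, 0.0, 0.0, 0.1,
    0.5, 1.2, 1.5, 0.8, 0.6, 0.9,
    1.4, 1.0, 0.7, 0.6, 0.8, 1.3,
    1.6, 1.1, 0.7, 0.4, 0.2, 0.1,
]


def build_rate_matrix(
    daily_bouts: float,
    hourly_weights: Sequence[float],
    dow_weights: Sequence[float],
) -> np.ndarray:
    """Build a 24x7 expected-bout-starts matrix from weight profiles.

    ``hourly_weights`` (24) set the within-day shape; ``dow_weights`` (7,
    Monday-first) scale whole days relative to each other.  The matrix is
    normalized so the *average* day totals ``daily_bouts`` expected starts.
    """
    hw = np.asarray(hourly_weights, dtype=float)
    dw = np.asarray(dow_weights, dtype=float)
    if hw.shape != (24,) or dw.shape != (7,):
        raise ConfigError("hourly_weights must have length 24, dow_weights length 7")
    if (hw < 0).any() or (dw < 0).any():
        raise ConfigError("rate weights must be non-negative")
    if hw.sum() == 0:
        return np.zeros((24, 7))
    col = hw / hw.sum()
    day_scale = dw * 7 / dw.sum() if dw.sum() > 0 else np.zeros(7)
    return daily_bouts * np.outer(col, day_scale)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one simulated cohort."""

    n_participants: int
    n_days: int = 43
    hourly_bout_rate: np.ndarray = field(default_factory=_default_rate)
    bout_duration: SampleSpec = field(default_factory=_default_bout_duration)
    active_cadence: SampleSpec = field(default_factory=_default_active_cadence)
    background_cadence: SampleSpec = field(default_factory=_default_background_cadence)
    background_minutes: SampleSpec = field(default_factory=_default_background_minutes)
    missing_day_prob: float = 0.369
    start_date: str = "2015-08-03"  # a Monday
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "hourly_bout_rate", np.asarray(self.hourly_bout_rate, dtype=float)
        )

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.hourly_bout_rate.shape != (24, 7):
            raise ConfigError("hourly_bout_rate must be 24x7 (hour-of-day x day-of-week)")
        if (self.hourly_bout_rate < 0).any():
            raise ConfigError("hourly_bout_rate entries must be >= 0")
        if not 0.0 <= self.missing_day_prob <= 1.0:
            raise ConfigError("missing_day_prob must be in [0, 1]")
        for spec in (
            self.bout_duration,
            self.active_cadence,
            self.background_cadence,
            self.background_minutes,
        ):
            spec.validate()
        if self.bout_duration.support_min < 5:
            raise ConfigError("bout_duration support must be >= 5 minutes")
        if self.active_cadence.support_min < 60:
            raise ConfigError("active_cadence support must be >= 60 steps/min")
        if self.background_cadence.support_max >= 60:
            raise ConfigError("background_cadence support must be < 60 steps/min")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class MinuteStepSeries:
    """One participant's minute-resolution step counts.

    ``steps`` is indexed by strictly increasing minute timestamps; values are
    non-negative integer step counts.  Days with no index entries at all are
    "missed days" (device not worn).
    """

    participant_id: str
    steps: pd.Series

    def __post_init__(self) -> None:
        idx = self.steps.index
        if len(idx) > 0:
            if not idx.is_monotonic_increasing or idx.has_duplicates:
                raise ValueError("timestamps must be strictly increasing")
            if (self.steps.to_numpy() < 0).any():
                raise ValueError("step counts must be non-negative")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def recorded_days(self) -> pd.DatetimeIndex:
        """Distinct calendar days having at least one record."""
        return pd.DatetimeIndex(self.steps.index.normalize().unique())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "timestamp": self.steps.index,
                "steps": self.steps.to_numpy(),
            }
        )


def _participant_rng(seed: int, participant_index: int) -> np.random.Generator:
    # Child stream keyed by (seed, index): stable under cohort-size changes.
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(participant_index,))
    return np.random.default_rng(ss)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or contiguous [start, end) minute intervals."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s <= pe:  # overlap or back-to-back: one uninterrupted >=60spm run
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def simulate_participant(
    config: GeneratorConfig, participant_index: int
) -> MinuteStepSeries:
    """Simulate one participant's stream, reproducible from (seed, index)."""
    config.validate()
    if not 0 <= participant_index < max(config.n_participants, 1):
        raise ConfigError("participant_index out of range")
    rng = _participant_rng(config.seed, participant_index)
    start = pd.Timestamp(config.start_date)
    start_dow = start.dayofweek

    missing = rng.random(config.n_days) < config.missing_day_prob

    minute_idx: list[np.ndarray] = []
    step_vals: list[np.ndarray] = []
    for day in range(config.n_days):
        if missing[day]:
            continue
        dow = (start_dow + day) % 7
        counts = rng.poisson(config.hourly_bout_rate[:, dow])
        intervals: list[tuple[int, int]] = []
        day_base = day * MINUTES_PER_DAY
        for hour in np.nonzero(counts)[0]:
            offsets = rng.integers(0, 60, counts[hour])
            durations = config.bout_duration.sample(rng, counts[hour])
            for off, dur in zip(offsets, durations):
                s = day_base + hour * 60 + int(off)
                intervals.append((s, min(s + int(dur), day_base + MINUTES_PER_DAY)))
        merged = _merge_intervals(intervals)
        bout_minutes = (
            np.concatenate([np.arange(s, e) for s, e in merged])
            if merged
            else np.empty(0, dtype=np.int64)
        )
        cadences = config.active_cadence.sample(rng, bout_minutes.size)

        n_bg = int(config.background_minutes.sample(rng, 1)[0])
        free = np.setdiff1d(
            np.arange(day_base, day_base + MINUTES_PER_DAY), bout_minutes
        )
        n_bg = min(n_bg, free.size)
        bg_minutes = rng.choice(free, size=n_bg, replace=False) if n_bg else free[:0]
        bg_steps = config.background_cadence.sample(rng, n_bg)

        day_minutes = np.concatenate([bout_minutes, bg_minutes])
        day_steps = np.concatenate([cadences, bg_steps])
        order = np.argsort(day_minutes)
        minute_idx.append(day_minutes[order])
        step_vals.append(day_steps[order])

    if minute_idx:
        minutes = np.concatenate(minute_idx)
        values = np.concatenate(step_vals).astype(np.int64)
    else:
        minutes = np.empty(0, dtype=np.int64)
        values = np.empty(0, dtype=np.int64)
    index = start + pd.to_timedelta(minutes, unit="min")
    return MinuteStepSeries(
        participant_id=f"P{participant_index:03d}",
        steps=pd.Series(values, index=index, name="steps"),
    )


def simulate_cohort(config: GeneratorConfig) -> list[MinuteStepSeries]:
    """Simulate all participants; deterministic given ``config.seed``."""
    config.validate()
    return [simulate_participant(config, i) for i in range(config.n_participants)]


@dataclass(frozen=True)
class CohortSummary:
    """Per-participant statistics averaged across a cohort (mean, SD)."""

    n_participants: int
    days_with_data: tuple[float, float]
    recorded_min_per_day: tuple[float, float]
    active_min_per_day: tuple[float, float]  # minutes at >= 60 steps/min
    bouts_per_day: tuple[float, float]
    mean_bout_length: tuple[float, float]
    walking_hours_per_day: tuple[float, float]
    fraction_missing_days: tuple[float, float]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k != "n_participants"
        }


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def summarize_cohort(
    cohort: Iterable[MinuteStepSeries],
    total_days: int | None = None,
    min_spm: int = 60,
    min_len: int = 5,
) -> CohortSummary:
    """Descriptive statistics of a cohort, computed per participant then averaged.

    ``total_days`` is the nominal study length used for the missing-day
    fraction; when None, each participant's observed span (first to last
    recorded day, inclusive) is used instead.
    """
    from .preprocess import detect_bouts  # local import avoids cycle at import time

    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")

    days, rec_min, act_min, bpd, blen, whrs, fmiss = ([] for _ in range(7))
    for series in cohort:
        rec_days = series.recorded_days
        n_rec = len(rec_days)
        if total_days is not None:
            span = total_days
        elif n_rec:
            span = int((rec_days.max() - rec_days.min()).days) + 1
        else:
            span = 0
        if span:
            fmiss.append((span - n_rec) / span)
        else:
            fmiss.append(1.0)
        days.append(float(n_rec))
        if n_rec == 0:
            rec_min.append(0.0)
            act_min.append(0.0)
            bpd.append(0.0)
            whrs.append(0.0)
            continue
        rec_min.append(len(series) / n_rec)
        act_min.append(float((series.steps.to_numpy() >= min_spm).sum()) / n_rec)
        bouts = detect_bouts(series, min_spm=min_spm, min_len=min_len)
        bpd.append(len(bouts) / n_rec)
        if bouts:
            blen.append(float(np.mean([b.duration_min for b in bouts])))
            hours = set()
            for b in bouts:
                h0 = b.start.floor("h")
                h1 = (b.start + pd.Timedelta(minutes=b.duration_min - 1)).floor("h")
                hours.update(pd.date_range(h0, h1, freq="h"))
            whrs.append(len(hours) / n_rec)
        else:
            whrs.append(0.0)

    return CohortSummary(
        n_participants=len(cohort),
        days_with_data=_mean_sd(days),
        recorded_min_per_day=_mean_sd(rec_min),
        active_min_per_day=_mean_sd(act_min),
        bouts_per_day=_mean_sd(bpd),
        mean_bout_length=_mean_sd(blen) if blen else (float("nan"), float("nan")),
        walking_hours_per_day=_mean_sd(whrs),
        fraction_missing_days=_mean_sd(fmiss),
    )


# ---------------------------------------------------------------------------
# Presets and I/O


def available_presets() -> list[str]:
    pkg = resources.files("walkcast.presets")
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str, **overrides) -> GeneratorConfig:
    """Load a shipped preset ("default", "null", "structured") as a config.

    Keyword overrides replace top-level config fields (e.g. ``seed=7``,
    ``n_participants=10``).
    """
    pkg = resources.files("walkcast.presets")
    try:
        text = (pkg / f"{name}.yaml").read_text()
    except FileNotFoundError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    raw = yaml.safe_load(text)
    rate = build_rate_matrix(
        daily_bouts=raw["daily_bouts"],
        hourly_weights=raw["hourly_weights"],
        dow_weights=raw["dow_weights"],
    )

    def spec(key: str, fallback) -> SampleSpec:
        if key in raw:
            return SampleSpec(raw[key]["family"], dict(raw[key]["params"]))
        return fallback

    cfg = GeneratorConfig(
        n_participants=raw.get("n_participants", 41),
        n_days=raw.get("n_days", 43),
        hourly_bout_rate=rate,
        bout_duration=spec("bout_duration", _default_bout_duration()),
        active_cadence=spec("active_cadence", _default_active_cadence()),
        background_cadence=spec("background_cadence", _default_background_cadence()),
        background_minutes=spec("background_minutes", _default_background_minutes()),
        missing_day_prob=raw.get("missing_day_prob", 0.369),
        start_date=raw.get("start_date", "2015-08-03"),
        seed=raw.get("seed", 0),
    )
    if overrides:
        cfg = cfg.replace(**overrides)
    cfg.validate()
    return cfg


def write_cohort_csv(cohort: Iterable[MinuteStepSeries], path: str | Path) -> None:
    """Write a cohort as delimited text: participant_id,timestamp,steps."""
    frames = [s.to_frame() for s in cohort]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["participant_id", "timestamp", "steps"])
    )
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
    out.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[MinuteStepSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    cohort = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        cohort.append(
            MinuteStepSeries(
                participant_id=str(pid),
                steps=pd.Series(
                    grp["steps"].to_numpy(dtype=np.int64),
                    index=pd.DatetimeIndex(grp["timestamp"]),
                    name="steps",
                ),
            )
        )
    return cohort
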