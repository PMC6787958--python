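"""Daily recording schedules: score-ranked optimized and stationary fixed.

The optimized allocator scores each clock hour of a site-day as the dot
product of the current species priority weights with the species' hourly
vocalization probabilities, ranks hours by score (ties broken toward the
earlier clock hour), and fills them greedily with 1-min samples: at most 30
samples per hour, evenly spaced (m samples start at minutes
``round(j * 60 / m)``), overflow cascading to the next-ranked hour.  The
30-per-hour cap and the >= 1-min buffer between samples reflect field
constraints on reliable transmission of short recordings over a cellular
network.

Fixed schedules are the stationary baselines shipped for sampling efforts
S in {2, 5, 10, 20, 30, 40}: identical across sites and days, clustered
around average sunrise and sunset times.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "MAX_SAMPLES_PER_HOUR",
    "SUPPORTED_FIXED_EFFORTS",
    "SiteHourScore",
    "DailySchedule",
    "score_site_hours",
    "allocate_counts",
    "allocate_samples",
    "fixed_schedule",
    "fixed_hour_counts",
    "schedules_to_frame",
]

#: Hard cap on 1-min samples in any single clock hour.
MAX_SAMPLES_PER_HOUR = 30

SUPPORTED_FIXED_EFFORTS = (2, 5, 10, 20, 30, 40)

_SAMPLE_SECONDS = 60


@dataclass(frozen=True)
class SiteHourScore:
    site_id: str
    date: dt.date
    hour_of_day: int
    score: float


@dataclass(frozen=True)
class DailySchedule:
    """The ordered 1-min sample start times for one site and day."""

    site_id: str
    date: dt.date
    sample_starts: tuple[dt.time, ...]

    def __post_init__(self) -> None:
        starts = sorted(
            t.hour * 3600 + t.minute * 60 + t.second for t in self.sample_starts
        )
        if list(starts) != [
            t.hour * 3600 + t.minute * 60 + t.second for t in self.sample_starts
        ]:
            object.__setattr__(
                self,
                "sample_starts",
                tuple(sorted(self.sample_starts)),
            )
        for a, b in zip(starts, starts[1:]):
            if b - a < 2 * _SAMPLE_SECONDS:
                raise ValueError(
                    f"samples at {a}s and {b}s overlap or lack a 1-min buffer"
                )
        counts = np.bincount([s // 3600 for s in starts], minlength=24)
        if counts.max(initial=0) > MAX_SAMPLES_PER_HOUR:
            raise ValueError(
                f"more than {MAX_SAMPLES_PER_HOUR} samples in one clock hour"
            )

    @property
    def effort(self) -> int:
        return len(self.sample_starts)

    def hour_counts(self) -> np.ndarray:
        """Number of samples falling in each of the 24 clock hours."""
        return np.bincount(
            [t.hour for t in self.sample_starts], minlength=24
        ).astype(np.int64)


def score_site_hours(
    pv_day: np.ndarray, weights: np.ndarray, site_id: str = "", date=None
) -> np.ndarray:
    """Score the 24 hours of one site-day: score_h = sum_k w_k * p_v[k, h].

    ``pv_day`` has shape (K, 24); ``weights`` shape (K,), all >= 0.
    """
    pv_day = np.asarray(pv_day, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if pv_day.ndim != 2 or pv_day.shape[1] != 24:
        raise ValueError(f"pv_day must be (K, 24), got {pv_day.shape}")
    if weights.shape != (pv_day.shape[0],):
        raise ValueError(
            f"weights length {weights.shape} does not match {pv_day.shape[0]} species"
        )
    if (weights < 0).any():
        raise ValueError("weights must be >= 0")
    return weights @ pv_day


def allocate_counts(scores: np.ndarray, effort: int) -> np.ndarray:
    """Greedy per-hour sample counts for one day.

    Hours are ranked by descending score (earlier hour wins ties) and each
    receives up to :data:`MAX_SAMPLES_PER_HOUR` samples until ``effort`` is
    exhausted.  Returns a length-24 integer array summing to ``effort``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (24,):
        raise ValueError(f"scores must have shape (24,), got {scores.shape}")
    if not 1 <= effort <= MAX_SAMPLES_PER_HOUR * 24:
        raise ValueError(
            f"effort must be in [1, {MAX_SAMPLES_PER_HOUR * 24}], got {effort}"
        )
    order = np.argsort(-scores, kind="stable")  # stable => earlier hour first on ties
    capacity = np.clip(
        effort - MAX_SAMPLES_PER_HOUR * np.arange(24), 0, MAX_SAMPLES_PER_HOUR
    )
    counts = np.zeros(24, dtype=np.int64)
    counts[order] = capacity
    return counts


def even_start_minutes(m: int) -> list[int]:
    """Start minutes for m evenly spaced 1-min samples within one hour."""
    if not 0 <= m <= MAX_SAMPLES_PER_HOUR:
        raise ValueError(f"m must be in [0, {MAX_SAMPLES_PER_HOUR}], got {m}")
    return [round(j * 60 / m) for j in range(m)]


def allocate_samples(
    scores: np.ndarray, effort: int, site_id: str = "", date: dt.date | None = None
) -> DailySchedule:
    """Build the optimized :class:`DailySchedule` for one site-day."""
    counts = allocate_counts(scores, effort)
    starts = [
        dt.time(hour, minute)
        for hour in range(24)
        for minute in even_start_minutes(int(counts[hour]))
    ]
    return DailySchedule(site_id, date or dt.date.today(), tuple(starts))


def _load_fixed() -> dict[int, tuple[dt.time, ...]]:
    ref = resources.files("adaptsample.data") / "fixed_schedules.csv"
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    out: dict[int, tuple[dt.time, ...]] = {}
    for effort, grp in df.groupby("effort"):
        times = tuple(
            dt.time.fromisoformat(t) for t in grp["start_time"].tolist()
        )
        out[int(effort)] = times
    return out


_FIXED_CACHE: dict[int, tuple[dt.time, ...]] | None = None


def fixed_schedule(
    effort: int, site_id: str = "", date: dt.date | None = None
) -> DailySchedule:
    """The stationary daily schedule for a supported sampling effort."""
    global _FIXED_CACHE
    if _FIXED_CACHE is None:
        _FIXED_CACHE = _load_fixed()
    if effort not in _FIXED_CACHE:
        raise ValueError(
            f"no fixed schedule for S={effort}; supported: "
            f"{sorted(_FIXED_CACHE)}"
        )
    return DailySchedule(site_id, date or dt.date.today(), _FIXED_CACHE[effort])


def fixed_hour_counts(effort: int) -> np.ndarray:
    """Per-hour sample counts of the fixed schedule for ``effort``."""
    return fixed_schedule(effort).hour_counts()


def schedules_to_frame(schedules) -> pd.DataFrame:
    """Flatten schedules to site_id, date, start_time, duration_s rows."""
    rows = [
        {
            "site_id": s.site_id,
            "date": pd.Timestamp(s.date).date().isoformat(),
            "start_time": t.isoformat(),
            "duration_s": _SAMPLE_SECONDS,
        }
        for s in schedules
        for t in s.sample_starts
    ]
    df = pd.DataFrame(rows, columns=["site_id", "date", "start_time", "duration_s"])
    return df.sort_values(["site_id", "date", "start_time"], kind="stable").reset_index(
        drop=True
    )
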