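"""Daily summaries of minute-level actigraphy.

A participant-day is a vector of 1440 per-minute intensity codes
(0 = non-wear, 1 = sedentary, 2 = light, 3 = moderate, 4 = vigorous).
This module turns such traces into the daily activity features used by the
stress models: wear time with the 10-hour validity rule, exercise bouts under
two window conventions (>=24 MVPA minutes out of 30, and >=8 out of 10), total
moderate-to-vigorous minutes, and the count of "active" clock hours.

Bout counting is greedy and non-overlapping: scanning left to right, the
earliest qualifying window claims its minutes and the scan resumes after its
end.  This makes the count deterministic and checkable against an exhaustive
all-windows oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NONWEAR = 0
SEDENTARY = 1
LIGHT = 2
MODERATE = 3
VIGOROUS = 4

MINUTES_PER_DAY = 1440
#: a day counts as analyzable only with at least 10 hours of wear
MIN_WEAR_MINUTES = 600
#: a clock hour is "active" with at least this many minutes at >= light intensity
ACTIVE_HOUR_MIN_MINUTES = 10

BOUT_30 = (30, 24)  # (window minutes, required MVPA minutes)
BOUT_10 = (10, 8)


def _validate_trace(trace: Sequence[int]) -> np.ndarray:
    arr = np.asarray(trace)
    if arr.ndim != 1 or arr.shape[0] != MINUTES_PER_DAY:
        raise ValueError(
            f"a minute trace must have exactly {MINUTES_PER_DAY} entries, got shape {arr.shape}"
        )
    return arr


def wear_minutes(trace: Sequence[int]) -> int:
    """Number of minutes the device registered wear (intensity != non-wear)."""
    arr = _validate_trace(trace)
    return int(np.count_nonzero(arr != NONWEAR))


def is_valid_day(trace: Sequence[int]) -> bool:
    """True when the day meets the 10-hour wear rule (>= 600 wear minutes)."""
    return wear_minutes(trace) >= MIN_WEAR_MINUTES


def detect_bouts(
    trace: Sequence[int], window: int, min_mvpa: int
) -> list[tuple[int, int]]:
    """Greedy non-overlapping exercise bouts.

    Returns ``(start_minute, mvpa_minutes)`` for each claimed window.  A window
    of ``window`` consecutive minutes qualifies when it contains at least
    ``min_mvpa`` minutes at moderate or vigorous intensity.  The earliest
    qualifying start claims a bout; scanning resumes at ``start + window``.
    """
    arr = _validate_trace(trace)
    mvpa = (arr >= MODERATE).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(mvpa)))
    wsum = csum[window:] - csum[:-window]  # MVPA minutes per window start
    qualifying = np.flatnonzero(wsum >= min_mvpa)
    bouts: list[tuple[int, int]] = []
    i = 0
    while i < qualifying.size:
        start = int(qualifying[i])
        bouts.append((start, int(wsum[start])))
        i = int(np.searchsorted(qualifying, start + window, side="left"))
    return bouts


def detect_bouts_30(trace: Sequence[int]) -> list[tuple[int, int]]:
    """Bouts under the 30-minute window / 24-MVPA-minute convention."""
    return detect_bouts(trace, *BOUT_30)


def detect_bouts_10(trace: Sequence[int]) -> list[tuple[int, int]]:
    """Bouts under the 10-minute window / 8-MVPA-minute convention."""
    return detect_bouts(trace, *BOUT_10)


def active_hours(trace: Sequence[int]) -> int:
    arr = _validate_trace(trace)
    per_hour = (arr.reshape(24, 60) >= LIGHT).sum(axis=1)
    return int(np.count_nonzero(per_hour >= ACTIVE_HOUR_MIN_MINUTES))


@dataclass(frozen=True)
class DailyActivity:
    """All per-day activity features derived from one minute trace."""

    person_id: str
    date: object  # datetime.date
    wear_min: int
    valid_day: bool
    n_bouts_30: int
    any_bout_30: bool
    exercise_min_in_bouts_30: int
    n_bouts_10: int
    any_bout_10: bool
    total_exercise_min: int
    active_hours: int


def daily_features(
    trace: Sequence[int], person_id: str = "", date: object = None
) -> DailyActivity:
    """Compute every :class:`DailyActivity` field for one trace."""
    arr = _validate_trace(trace)
    wear = wear_minutes(arr)
    b30 = detect_bouts_30(arr)
    b10 = detect_bouts_10(arr)
    return DailyActivity(
        person_id=person_id,
        date=date,
        wear_min=wear,
        valid_day=wear >= MIN_WEAR_MINUTES,
        n_bouts_30=len(b30),
        any_bout_30=len(b30) >= 1,
        exercise_min_in_bouts_30=int(sum(m for _, m in b30)),
        n_bouts_10=len(b10),
        any_bout_10=len(b10) >= 1,
        total_exercise_min=int(np.count_nonzero(arr >= MODERATE)),
        active_hours=active_hours(arr),
    )


def daily_table(records: Iterable[tuple[str, object, Sequence[int]]]) -> pd.DataFrame:
    """Tabulate :func:`daily_features` over ``(person_id, date, trace)`` records."""
    rows = [daily_features(trace, person_id, date) for person_id, date, trace in records]
    cols = [f.name for f in fields(DailyActivity)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in rows], columns=cols)


def read_minutes_csv(path) -> pd.DataFrame:
    """Read the long-format minutes table (person_id, date, minute_index, intensity_code)."""
    df = pd.read_csv(path, parse_dates=["date"])
    df["date"] = df["date"].dt.date
    return df


def daily_table_from_minutes(minutes: pd.DataFrame) -> pd.DataFrame:
    """Daily features from a long-format minutes table (one row per minute)."""

    def _records():
        for (pid, date), grp in minutes.groupby(["person_id", "date"], sort=True):
            trace = np.zeros(MINUTES_PER_DAY, dtype=np.int8)
            trace[grp["minute_index"].to_numpy()] = grp["intensity_code"].to_numpy()
            yield str(pid), date, trace

    return daily_table(_records())
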