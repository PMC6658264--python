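"""Lagged prediction samples, chronological splits, and person-specific
binarization.

Each sample predicts the stress rating on a target day from weather on the
target day and the previous 3 days (lags 0-3), and from stress ratings and
daily activity features on the previous 3 days (lags 1-3).  A target day is
eligible only when its own rating and all three lagged ratings are observed,
and (by default) the three lagged days pass the 10-hour wear rule.  Day of
week is one-hot encoded; in nomothetic mode the static person covariates
(age, sex, height, weight) are appended.

The split is strictly chronological per person — the first ceil(p*n) eligible
samples train, the rest test — and the high-stress threshold for binarization
is that person's median training rating.  Every fitted statistic (medians,
scaler moments) records the training date range it was computed from, so
leakage is checkable structurally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

WEATHER_VARS = ["tmin_f", "tmax_f", "tavg_f", "temp_range_f", "daylight_min", "precip_in"]
ACTIVITY_VARS = [
    "active_hours",
    "exercise_min_in_bouts_30",
    "n_bouts_30",
    "any_bout_30",
    "n_bouts_10",
    "any_bout_10",
    "total_exercise_min",
]
PERSON_VARS = ["age", "sex", "height_cm", "weight_kg"]
DOW_VARS = [f"dow_{k}" for k in range(7)]

ID_COLS = ["person_id", "target_date", "y"]

DEFAULT_WEATHER_LAGS = (0, 1, 2, 3)
DEFAULT_HISTORY_LAGS = (1, 2, 3)


def feature_columns(
    mode: str = "nomothetic",
    weather_lags: Sequence[int] = DEFAULT_WEATHER_LAGS,
    history_lags: Sequence[int] = DEFAULT_HISTORY_LAGS,
) -> list[str]:
    """Canonical ordered feature list for a sample table."""
    cols = [f"stress_lag{k}" for k in history_lags]
    cols += [f"{v}_lag{k}" for k in weather_lags for v in WEATHER_VARS]
    cols += [f"{v}_lag{k}" for k in history_lags for v in ACTIVITY_VARS]
    cols += list(DOW_VARS)
    if mode == "nomothetic":
        cols += list(PERSON_VARS)
    elif mode != "ideographic":
        raise ValueError(f"mode must be 'nomothetic' or 'ideographic', got {mode!r}")
    return cols


def feature_family(name: str) -> str:
    """Map a feature column to its scientific family."""
    base = name.split("_lag")[0]
    if base == "stress":
        return "stress"
    if base in ("tmin_f", "tmax_f", "tavg_f", "temp_range_f"):
        return "temperature"
    if base == "daylight_min":
        return "daylight"
    if base == "precip_in":
        return "precipitation"
    if base in ACTIVITY_VARS:
        return "exercise"
    if name.startswith("dow_"):
        return "day_of_week"
    if name in PERSON_VARS:
        return "person"
    raise KeyError(f"unknown feature {name!r}")


def build_samples(
    stress: pd.DataFrame,
    activity: pd.DataFrame,
    weather: pd.DataFrame,
    mode: str = "nomothetic",
    persons: Optional[pd.DataFrame] = None,
    weather_lags: Sequence[int] = DEFAULT_WEATHER_LAGS,
    history_lags: Sequence[int] = DEFAULT_HISTORY_LAGS,
    require_valid_activity: bool = True,
) -> pd.DataFrame:
    """Assemble eligible lagged samples from the raw per-day tables.

    ``stress`` needs (person_id, date, rating); ``activity`` the DailyActivity
    columns; ``weather`` one row per calendar date.  A sample exists for day t
    iff rating(t) and rating(t-1..t-3) are observed and (when
    ``require_valid_activity``) the activity days t-1..t-3 are valid.
    """
    if mode == "nomothetic" and persons is None:
        raise ValueError("nomothetic mode needs the persons table for covariates")
    max_lag = max(tuple(weather_lags) + tuple(history_lags))
    wx = weather.set_index("date")
    parts = []
    for pid, sub in stress.groupby("person_id", sort=True):
        sub = sub.sort_values("date")
        dates = pd.Index(sub["date"])
        full = pd.date_range(dates.min(), dates.max(), freq="D").date
        s = sub.set_index("date").reindex(full)
        act = (
            activity[activity["person_id"] == pid]
            .set_index("date")
            .reindex(full)
        )
        w = wx.reindex(full)

        rating = s["rating"]
        valid = act["valid_day"].fillna(False).astype(bool)
        eligible = rating.notna()
        for k in (1, 2, 3):
            eligible &= rating.shift(k).notna().to_numpy()
            if require_valid_activity:
                eligible &= valid.shift(k, fill_value=False).to_numpy()
        eligible = eligible.to_numpy()
        eligible[:max_lag] = False
        if not eligible.any():
            continue

        data = {
            "person_id": pid,
            "target_date": np.asarray(full, dtype=object),
            "y": rating.to_numpy(float),
        }
        for k in history_lags:
            data[f"stress_lag{k}"] = rating.shift(k).to_numpy(float)
        for k in weather_lags:
            for v in WEATHER_VARS:
                data[f"{v}_lag{k}"] = w[v].shift(k).to_numpy(float)
        for k in history_lags:
            for v in ACTIVITY_VARS:
                data[f"{v}_lag{k}"] = (
                    act[v].shift(k).to_numpy(float)
                )
        dow = np.array([d.weekday() for d in full])
        for j in range(7):
            data[f"dow_{j}"] = (dow == j).astype(float)
        df = pd.DataFrame(data).loc[eligible].reset_index(drop=True)
        parts.append(df)

    if not parts:
        cols = ID_COLS + feature_columns(mode, weather_lags, history_lags)
        return pd.DataFrame(columns=cols)
    samples = pd.concat(parts, ignore_index=True)
    if mode == "nomothetic":
        cov = persons.set_index("person_id")[PERSON_VARS]
        samples = samples.join(cov, on="person_id")
    samples["y"] = samples["y"].astype(int)
    cols = ID_COLS + feature_columns(mode, weather_lags, history_lags)
    return samples[cols]


# ---------------------------------------------------------------------------
# chronological split
# ---------------------------------------------------------------------------


@dataclass
class SplitSpec:
    """A per-person chronological train/test partition."""

    proportion: float
    train: pd.DataFrame
    test: pd.DataFrame
    dropped_persons: list[str] = field(default_factory=list)

    def train_date_range(self, person_id: str) -> tuple:
        sub = self.train.loc[self.train["person_id"] == person_id, "target_date"]
        return (sub.min(), sub.max())


def chronological_split(samples: pd.DataFrame, proportion: float) -> SplitSpec:
    """First ceil(p*n) samples per person train, the remainder test.

    Persons left without at least one training and one test sample are
    dropped from evaluation entirely.
    """
    if not 0 < proportion < 1:
        raise ValueError("proportion must lie strictly between 0 and 1")
    train_parts, test_parts, dropped = [], [], []
    for pid, sub in samples.groupby("person_id", sort=True):
        sub = sub.sort_values("target_date")
        n = len(sub)
        n_train = math.ceil(proportion * n)
        if n_train < 1 or n - n_train < 1:
            dropped.append(pid)
            continue
        train_parts.append(sub.iloc[:n_train])
        test_parts.append(sub.iloc[n_train:])
    empty = samples.iloc[0:0]
    return SplitSpec(
        proportion=proportion,
        train=pd.concat(train_parts, ignore_index=True) if train_parts else empty.copy(),
        test=pd.concat(test_parts, ignore_index=True) if test_parts else empty.copy(),
        dropped_persons=dropped,
    )


# ---------------------------------------------------------------------------
# thresholds and binarization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StressThreshold:
    """A person's high-stress cut point: the median training rating."""

    person_id: str
    median_train: float
    train_date_range: tuple


def compute_thresholds(train: pd.DataFrame) -> dict[str, StressThreshold]:
    """Per-person medians of the training-set ratings (training rows only)."""
    out = {}
    for pid, sub in train.groupby("person_id", sort=True):
        out[pid] = StressThreshold(
            person_id=pid,
            median_train=float(sub["y"].median()),
            train_date_range=(sub["target_date"].min(), sub["target_date"].max()),
        )
    return out


def binarize(values, threshold: StressThreshold, ties: str = "below") -> np.ndarray:
    """1 iff strictly above the person's training median (ties -> class 0).

    ``ties='above'`` flips the tie rule (value == median -> class 1).
    """
    v = np.asarray(values, dtype=float)
    if ties == "below":
        out = v > threshold.median_train
    elif ties == "above":
        out = v >= threshold.median_train
    else:
        raise ValueError("ties must be 'below' or 'above'")
    return out.astype(int)


def binarize_frame(
    df: pd.DataFrame,
    values: np.ndarray,
    thresholds: dict[str, StressThreshold],
    ties: str = "below",
) -> np.ndarray:
    """Binarize a value per row of a sample frame using each row's person."""
    out = np.empty(len(df), dtype=int)
    v = np.asarray(values, dtype=float)
    for pid, idx in df.groupby("person_id", sort=False).indices.items():
        out[idx] = binarize(v[idx], thresholds[pid], ties=ties)
    return out


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass
class Scaler:
    """Feature standardizer fitted on training rows only."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    train_date_range: tuple

    @classmethod
    def fit(cls, train: pd.DataFrame, columns: Sequence[str]) -> "Scaler":
        X = train[list(columns)].to_numpy(float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant columns pass through centred
        return cls(
            columns=list(columns),
            mean=mean,
            sd=sd,
            train_date_range=(train["target_date"].min(), train["target_date"].max()),
        )

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        X = out[self.columns].to_numpy(float)
        out[self.columns] = (X - self.mean) / self.sd
        return out
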