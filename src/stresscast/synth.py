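"""Synthetic EMA/actigraphy/weather cohorts.

The real study population (daily 0-10 stress self-reports, wrist-worn activity
tracking, and New York City weather over up to one year) was never deposited,
so every downstream stage of this package is exercised on synthetic cohorts
that reproduce the statistical structure the analysis relies on:

* integer 0-10 stress ratings with person-specific location, day-to-day
  autocorrelation, and restricted range use (some people never rate above a
  personal ceiling such as 7);
* heterogeneous, sign-varying weather effects and (mostly stress-reducing)
  exercise effects;
* seasonal temperature and daylight, zero-inflated precipitation;
* whole-day device non-wear, which trips the 10-hour wear rule;
* missing-not-at-random stress reports: the probability that a rating is
  missing increases with the latent stress that day, so missing days genuinely
  hide higher stress.

The generative stress process is a latent Gaussian AR(1),

    latent_t = b + phi*(latent_{t-1} - b) + beta_T*(tavg_t - mean(tavg))
             + beta_D*(daylight_t - mean(daylight)) + beta_E*bouts_t + eps_t,

observed rating = clamp(round(latent_t), 0, ceiling), then masked missing with
probability logistic(logit(miss_base) + miss_stress_slope * latent_t).

All randomness flows from a single root seed through named substreams, so a
(config, seed) pair maps to a byte-identical cohort.
"""

from __future__ import annotations

import dataclasses
import datetime
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import actigraphy

DAYS_PER_YEAR = 365.25
#: substream tags hung off the root SeedSequence
_WEATHER_STREAM = 0
_PERSON_STREAM = 1


class ConfigError(ValueError):
    """Raised for impossible or inconsistent cohort configurations."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PersonParams:
    """True generative parameters for one synthetic participant."""

    person_id: str
    baseline_stress: float = 3.0
    ar_coef: float = 0.3            # day-to-day stress autocorrelation, [0, 1)
    temp_effect: float = 0.0        # stress points per deg F (sign varies)
    daylight_effect: float = 0.0    # stress points per daylight minute
    exercise_effect: float = 0.0    # stress points per same-day exercise bout
    noise_sd: float = 1.0
    scale_ceiling: int = 10         # highest rating the person ever uses
    miss_base: float = 0.1          # missingness probability anchor
    miss_stress_slope: float = 0.0  # MNAR link, >= 0
    exercise_rate: float = 2.0      # expected exercise bouts per week
    exercise_persistence: float = 0.0  # lag-1 autocorrelation of exercise days
    nonwear_prob: float = 0.05      # probability of a whole-day non-wear day
    age: float = 32.0
    sex: int = 0
    height_cm: float = 169.0
    weight_kg: float = 75.0

    def __post_init__(self):
        if not self.noise_sd >= 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0 <= self.miss_base < 1:
            raise ConfigError("miss_base must lie in [0, 1)")
        if not 0 <= self.ar_coef < 1:
            raise ConfigError("ar_coef must lie in [0, 1)")
        if not 0 <= self.scale_ceiling <= 10:
            raise ConfigError("scale_ceiling must lie in 0..10")
        if self.miss_stress_slope < 0:
            raise ConfigError("miss_stress_slope must be >= 0")
        if not 0 <= self.exercise_persistence < 1:
            raise ConfigError("exercise_persistence must lie in [0, 1)")


@dataclass(frozen=True)
class WeatherConfig:
    """Sinusoidal seasonal weather model (deg F, inches, minutes)."""

    mean_temp_f: float = 55.0
    temp_amplitude_f: float = 20.0   # seasonal swing, peak in late July
    temp_noise_sd: float = 5.0
    diurnal_half_range_f: tuple[float, float] = (5.0, 15.0)
    daylight_mean_min: float = 720.0
    daylight_amplitude_min: float = 180.0  # peak at the June solstice
    precip_prob: float = 0.3
    precip_mean_in: float = 0.25


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class CohortConfig:
    """Distributions from which per-person parameters are drawn.

    Ranges are uniform (low, high); ``temp_effect`` and ``daylight_effect``
    draw a magnitude from their range and a random sign, producing the
    sign-varying heterogeneity the analysis is designed around.
    """

    n_persons: int = 77
    n_days: int = 365
    start_day_of_year: int = 1
    start_date: datetime.date = datetime.date(2014, 1, 1)
    weather: WeatherConfig = field(default_factory=WeatherConfig)

    min_participation_days: int = 60
    max_participation_days: int = 365
    #: optional bimodal participation: a fixed count of persons (taken first
    #: by index, though parameters are still drawn independently) get long
    #: records from a separate range (0 -> single uniform range for everyone)
    n_long_records: int = 0
    long_participation_days: tuple[int, int] = (150, 200)

    baseline_range: tuple[float, float] = (2.0, 5.0)
    ar_range: tuple[float, float] = (0.1, 0.5)
    temp_effect_mag_range: tuple[float, float] = (0.0, 0.12)
    daylight_effect_mag_range: tuple[float, float] = (0.0, 0.006)
    exercise_effect_range: tuple[float, float] = (-0.8, 0.0)
    noise_sd_range: tuple[float, float] = (0.8, 1.5)
    scale_ceiling_choices: tuple[int, ...] = (7, 8, 9, 10, 10, 10)
    miss_base_range: tuple[float, float] = (0.05, 0.2)
    miss_stress_slope_range: tuple[float, float] = (0.0, 0.3)
    exercise_rate_range: tuple[float, float] = (1.0, 4.0)
    exercise_persistence_range: tuple[float, float] = (0.0, 0.5)
    nonwear_prob_range: tuple[float, float] = (0.0, 0.1)
    age_range: tuple[float, float] = (20.0, 58.0)
    height_range: tuple[float, float] = (149.0, 187.0)
    weight_range: tuple[float, float] = (43.0, 139.0)

    background_mvpa_rate: float = 0.01
    light_rate: float = 0.15

    #: persons whose observed ratings have variance below this are re-drawn
    min_rating_variance: float = 0.05
    min_observed_ratings: int = 10
    max_redraws: int = 20

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ConfigError("n_persons must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.min_participation_days > min(self.max_participation_days, self.n_days):
            raise ConfigError("participation range is empty for this n_days")
        for name in (
            "baseline_range", "ar_range", "temp_effect_mag_range",
            "daylight_effect_mag_range", "exercise_effect_range", "noise_sd_range",
            "miss_base_range", "miss_stress_slope_range", "exercise_rate_range",
            "exercise_persistence_range", "nonwear_prob_range", "age_range",
            "height_range", "weight_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} has low > high: ({lo}, {hi})")
        if any(not 0 <= c <= 10 for c in self.scale_ceiling_choices):
            raise ConfigError("scale_ceiling_choices must lie in 0..10")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        """Build from a (YAML-loaded) mapping; unknown keys are rejected."""
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
        if "weather" in d and isinstance(d["weather"], dict):
            wknown = {f.name for f in dataclasses.fields(WeatherConfig)}
            wunknown = set(d["weather"]) - wknown
            if wunknown:
                raise ConfigError(f"unknown weather config keys: {sorted(wunknown)}")
            d["weather"] = WeatherConfig(**d["weather"])
        if "start_date" in d and isinstance(d["start_date"], str):
            d["start_date"] = datetime.date.fromisoformat(d["start_date"])
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    # -- named study regimes -------------------------------------------------

    @classmethod
    def high_heterogeneity(cls, n_persons: int = 60) -> "CohortConfig":
        """Regime designed to exhibit the nomothetic/ideographic crossover.

        Sign-varying person-specific temperature effects that a pooled model
        cannot exploit, moderate stress autocorrelation and a consistent
        exercise effect that it can, and mostly short records (where
        per-person trees overfit) with a minority of long records (where the
        personal response becomes learnable).  Temperature variation is
        mostly day-to-day noise rather than seasonal drift, so lagged stress
        cannot proxy for the person-specific temperature response.
        """
        return cls(
            n_persons=n_persons,
            n_days=365,
            min_participation_days=30,
            max_participation_days=80,
            n_long_records=max(1, round(0.15 * n_persons)),
            long_participation_days=(180, 240),
            weather=WeatherConfig(temp_amplitude_f=5.0, temp_noise_sd=10.0),
            baseline_range=(2.5, 4.5),
            ar_range=(0.25, 0.45),
            temp_effect_mag_range=(0.11, 0.16),
            daylight_effect_mag_range=(0.0, 0.002),
            exercise_effect_range=(-1.2, -0.5),
            noise_sd_range=(0.9, 1.2),
            miss_base_range=(0.05, 0.1),
            miss_stress_slope_range=(0.0, 0.1),
            exercise_persistence_range=(0.3, 0.6),
            nonwear_prob_range=(0.0, 0.05),
        )

    @classmethod
    def dominant_driver(cls, n_persons: int = 25) -> "CohortConfig":
        """Regime where each person has one dominant generative driver.

        Used for parameter-recovery checks: long low-missingness records in
        which a single feature family (temperature, daylight, or exercise)
        drives most of the day-to-day stress variance.  Per-person driver
        assignment happens in :func:`generate_cohort` via
        ``dominant_driver_params``.
        """
        return cls(
            n_persons=n_persons,
            n_days=320,
            min_participation_days=260,
            max_participation_days=320,
            # mostly non-seasonal temperature so the temperature and daylight
            # drivers are statistically identifiable from each other
            weather=WeatherConfig(temp_amplitude_f=6.0, temp_noise_sd=10.0),
            baseline_range=(3.0, 5.0),
            ar_range=(0.0, 0.1),
            noise_sd_range=(0.5, 0.7),
            miss_base_range=(0.02, 0.05),
            miss_stress_slope_range=(0.0, 0.05),
            nonwear_prob_range=(0.0, 0.02),
            scale_ceiling_choices=(9, 10),
        )


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------


def generate_weather(
    n_days: int,
    start_day_of_year: int = 1,
    seed: int = 0,
    config: Optional[WeatherConfig] = None,
    start_date: Optional[datetime.date] = None,
) -> pd.DataFrame:
    """Seasonal daily weather series.

    Average temperature follows mean + amplitude * cos(phase from late July)
    plus Gaussian noise; min/max are placed symmetrically around the average
    with a random half-range, so tmin <= tavg <= tmax always holds.  Daylight
    is a solstice-anchored sinusoid; precipitation is zero-inflated
    exponential.
    """
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    if not 1 <= start_day_of_year <= 366:
        raise ConfigError("start_day_of_year must lie in 1..366")
    cfg = config or WeatherConfig()
    rng = _rng(seed, _WEATHER_STREAM)

    t = np.arange(n_days)
    doy = (start_day_of_year - 1 + t) % 365 + 1
    tavg = (
        cfg.mean_temp_f
        + cfg.temp_amplitude_f * np.cos(2 * np.pi * (doy - 202) / DAYS_PER_YEAR)
        + rng.normal(0.0, cfg.temp_noise_sd, n_days)
    )
    half = rng.uniform(*cfg.diurnal_half_range_f, n_days)
    tmin = tavg - half
    tmax = tavg + half
    daylight = np.clip(
        cfg.daylight_mean_min
        + cfg.daylight_amplitude_min * np.cos(2 * np.pi * (doy - 172) / DAYS_PER_YEAR),
        0.0,
        actigraphy.MINUTES_PER_DAY,
    )
    precip = np.where(
        rng.random(n_days) < cfg.precip_prob,
        rng.exponential(cfg.precip_mean_in, n_days),
        0.0,
    )
    if start_date is None:
        start_date = datetime.date(2014, 1, 1) + datetime.timedelta(
            days=start_day_of_year - 1
        )
    dates = [start_date + datetime.timedelta(days=int(k)) for k in t]
    return pd.DataFrame(
        {
            "date": dates,
            "tmin_f": tmin,
            "tmax_f": tmax,
            "tavg_f": tavg,
            "temp_range_f": tmax - tmin,
            "daylight_min": daylight,
            "precip_in": precip,
            "day_of_week": [d.weekday() for d in dates],
        }
    )


# ---------------------------------------------------------------------------
# minute traces
# ---------------------------------------------------------------------------


def generate_minute_trace(
    params: PersonParams,
    exercise_today: bool,
    rng: np.random.Generator,
    background_mvpa_rate: float = 0.01,
    light_rate: float = 0.15,
) -> np.ndarray:
    """One participant-day of 1440 intensity codes.

    Sleep (midnight-6am, 11pm-midnight) is non-wear; waking minutes are mostly
    sedentary with scattered light activity and a small background MVPA rate.
    On exercise days a contiguous block of 24-40 moderate/vigorous minutes is
    inserted, which guarantees at least one 24-of-30 bout.  With probability
    ``params.nonwear_prob`` the day is a non-wear day: wear is truncated to
    under 10 hours (leaving more than 14 hours of non-wear), so the day fails
    the wear rule.
    """
    trace = np.full(actigraphy.MINUTES_PER_DAY, actigraphy.SEDENTARY, dtype=np.int8)
    trace[:360] = actigraphy.NONWEAR
    trace[1380:] = actigraphy.NONWEAR
    wake = slice(360, 1380)
    u = rng.random(1380 - 360)
    seg = trace[wake]
    seg[u < light_rate] = actigraphy.LIGHT
    seg[u > 1.0 - background_mvpa_rate] = actigraphy.MODERATE
    trace[wake] = seg

    nonwear_day = rng.random() < params.nonwear_prob
    if nonwear_day:
        wear_len = int(rng.integers(120, 540))  # < 600 -> invalid day
        trace[360 + wear_len:] = actigraphy.NONWEAR

    if exercise_today:
        dur = int(rng.integers(24, 41))
        if nonwear_day:
            start = 360 + int(rng.integers(0, max(1, wear_len - dur)))
        else:
            start = int(rng.integers(380, 1340 - dur))
        block = rng.choice(
            [actigraphy.MODERATE, actigraphy.VIGOROUS], size=dur, p=[0.7, 0.3]
        )
        trace[start:start + dur] = block
    return trace


def _exercise_days(
    params: PersonParams, n_days: int, rng: np.random.Generator
) -> np.ndarray:
    """Exercise-day indicator with optional Markov persistence.

    Stationary probability is exercise_rate/7; ``exercise_persistence`` is the
    lag-1 autocorrelation of the two-state chain (0 = independent days).
    """
    pi = min(max(params.exercise_rate / 7.0, 0.0), 1.0)
    c = params.exercise_persistence
    u = rng.random(n_days)
    days = np.zeros(n_days, dtype=bool)
    if n_days == 0:
        return days
    days[0] = u[0] < pi
    p11 = pi + c * (1 - pi)
    p01 = pi * (1 - c)
    for t in range(1, n_days):
        days[t] = u[t] < (p11 if days[t - 1] else p01)
    return days


# ---------------------------------------------------------------------------
# stress series
# ---------------------------------------------------------------------------


def generate_stress_series(
    params: PersonParams,
    weather: pd.DataFrame,
    activity_features: pd.DataFrame,
    rng: np.random.Generator,
    temp_center: Optional[float] = None,
    daylight_center: Optional[float] = None,
) -> pd.DataFrame:
    """Latent AR(1) stress with rounding, ceiling clamping, and MNAR masking.

    Returns a frame with ``latent`` (the unobserved continuous stress),
    ``rating`` (observed 0..ceiling integer, NaN when missing) and
    ``missing``.  Weather effects are centred on the provided series means
    unless explicit centres are given.
    """
    n = len(weather)
    if len(activity_features) != n:
        raise ConfigError("weather and activity sequences must have equal length")
    tavg = weather["tavg_f"].to_numpy(float)
    daylight = weather["daylight_min"].to_numpy(float)
    bouts = activity_features["n_bouts_30"].to_numpy(float)
    t_bar = float(np.mean(tavg)) if temp_center is None else temp_center
    d_bar = float(np.mean(daylight)) if daylight_center is None else daylight_center

    noise = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)
    drive = (
        params.temp_effect * (tavg - t_bar)
        + params.daylight_effect * (daylight - d_bar)
        + params.exercise_effect * bouts
    )
    latent = np.empty(n)
    prev = params.baseline_stress
    for t in range(n):
        latent[t] = (
            params.baseline_stress
            + params.ar_coef * (prev - params.baseline_stress)
            + drive[t]
            + noise[t]
        )
        prev = latent[t]

    rating = np.clip(np.round(latent), 0, params.scale_ceiling)
    if params.miss_base > 0 or params.miss_stress_slope > 0:
        base_logit = logit(params.miss_base) if params.miss_base > 0 else -np.inf
        p_miss = expit(base_logit + params.miss_stress_slope * latent)
        missing = rng.random(n) < p_miss
    else:
        missing = np.zeros(n, dtype=bool)
    observed = rating.astype(float)
    observed[missing] = np.nan
    return pd.DataFrame({"latent": latent, "rating": observed, "missing": missing})


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A fully generated synthetic cohort."""

    config: CohortConfig
    seed: int
    persons: pd.DataFrame   # true generative parameters per person
    weather: pd.DataFrame
    stress: pd.DataFrame    # person_id, date, rating, latent, missing
    activity: pd.DataFrame  # DailyActivity fields per person-day
    traces: dict[str, np.ndarray]  # person_id -> (n_days, 1440) int8

    def write(self, outdir, minutes: bool = True) -> None:
        """Write the CSV bundle (weather, stress, persons, daily activity,
        and optionally the gzipped long-format minutes table)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.weather.to_csv(outdir / "weather.csv", index=False)
        self.stress[["person_id", "date", "rating"]].to_csv(
            outdir / "stress.csv", index=False
        )
        self.persons.to_csv(outdir / "persons.csv", index=False)
        self.activity.to_csv(outdir / "daily_activity.csv", index=False)
        if minutes:
            self._write_minutes(outdir / "minutes.csv.gz")

    def _write_minutes(self, path) -> None:
        with gzip.open(path, "wt", newline="") as fh:
            fh.write("person_id,date,minute_index,intensity_code\n")
            for pid, mat in self.traces.items():
                dates = self.stress.loc[
                    self.stress["person_id"] == pid, "date"
                ].tolist()
                for d, row in zip(dates, mat):
                    nz = np.flatnonzero(row)  # non-wear minutes are implicit zeros
                    for m in nz:
                        fh.write(f"{pid},{d.isoformat()},{m},{row[m]}\n")


def draw_person_params(
    config: CohortConfig, rng: np.random.Generator, person_id: str
) -> PersonParams:
    sign_t = rng.choice([-1.0, 1.0])
    sign_d = rng.choice([-1.0, 1.0])
    return PersonParams(
        person_id=person_id,
        baseline_stress=rng.uniform(*config.baseline_range),
        ar_coef=rng.uniform(*config.ar_range),
        temp_effect=sign_t * rng.uniform(*config.temp_effect_mag_range),
        daylight_effect=sign_d * rng.uniform(*config.daylight_effect_mag_range),
        exercise_effect=rng.uniform(*config.exercise_effect_range),
        noise_sd=rng.uniform(*config.noise_sd_range),
        scale_ceiling=int(rng.choice(config.scale_ceiling_choices)),
        miss_base=rng.uniform(*config.miss_base_range),
        miss_stress_slope=rng.uniform(*config.miss_stress_slope_range),
        exercise_rate=rng.uniform(*config.exercise_rate_range),
        exercise_persistence=rng.uniform(*config.exercise_persistence_range),
        nonwear_prob=rng.uniform(*config.nonwear_prob_range),
        age=float(np.round(rng.uniform(*config.age_range), 1)),
        sex=int(rng.integers(0, 2)),
        height_cm=float(np.round(rng.uniform(*config.height_range), 1)),
        weight_kg=float(np.round(rng.uniform(*config.weight_range), 1)),
    )


def dominant_driver_params(
    config: CohortConfig, rng: np.random.Generator, person_id: str, driver: str
) -> PersonParams:
    """Person parameters with a single dominant generative driver.

    ``driver`` is one of ``temperature``, ``daylight``, ``exercise``.  The
    chosen effect is made large relative to the noise; the other two are
    zeroed.  Exercise-driver persons exercise often and in multi-day streaks
    so that lagged activity features carry the signal.
    """
    base = draw_person_params(config, rng, person_id)
    sign = rng.choice([-1.0, 1.0])
    kwargs = dict(
        temp_effect=0.0,
        daylight_effect=0.0,
        exercise_effect=0.0,
        exercise_persistence=0.0,
    )
    if driver == "temperature":
        kwargs["temp_effect"] = sign * rng.uniform(0.12, 0.2)
    elif driver == "daylight":
        kwargs["daylight_effect"] = sign * rng.uniform(0.008, 0.014)
    elif driver == "exercise":
        kwargs["exercise_effect"] = -rng.uniform(2.5, 3.5)
        kwargs["exercise_persistence"] = rng.uniform(0.65, 0.8)
        kwargs["exercise_rate"] = rng.uniform(3.0, 4.0)
    else:
        raise ConfigError(f"unknown driver {driver!r}")
    return dataclasses.replace(base, **kwargs)


def _generate_person(
    config: CohortConfig,
    weather: pd.DataFrame,
    params: PersonParams,
    rng: np.random.Generator,
    long_record: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Traces, daily activity, and stress for one person over a random
    participation window of the cohort weather series."""
    if long_record:
        lo, hi = config.long_participation_days
        length = int(rng.integers(lo, min(hi, config.n_days) + 1))
    else:
        length = int(
            rng.integers(
                config.min_participation_days,
                min(config.max_participation_days, config.n_days) + 1,
            )
        )
    start = int(rng.integers(0, config.n_days - length + 1))
    wx = weather.iloc[start:start + length].reset_index(drop=True)
    ex_days = _exercise_days(params, length, rng)
    traces = np.stack(
        [
            generate_minute_trace(
                params,
                bool(ex_days[t]),
                rng,
                background_mvpa_rate=config.background_mvpa_rate,
                light_rate=config.light_rate,
            )
            for t in range(length)
        ]
    )
    activity = actigraphy.daily_table(
        (params.person_id, wx["date"].iloc[t], traces[t]) for t in range(length)
    )
    stress = generate_stress_series(
        params,
        wx,
        activity,
        rng,
        temp_center=float(weather["tavg_f"].mean()),
        daylight_center=float(weather["daylight_min"].mean()),
    )
    stress.insert(0, "date", wx["date"].to_numpy())
    stress.insert(0, "person_id", params.person_id)
    return stress, activity, traces


def generate_cohort(
    config: Optional[CohortConfig] = None,
    seed: int = 0,
    drivers: Optional[list[str]] = None,
) -> Cohort:
    """Generate a full synthetic cohort.

    Persons whose observed ratings have too few responses or (near-)zero
    variance are excluded and re-drawn, mirroring the exclusion of
    near-constant responders from the analysis sample.  ``drivers`` optionally
    assigns each person a dominant generative driver (cycled over the list);
    see :func:`dominant_driver_params`.
    """
    config = config or CohortConfig()
    config.validate()
    weather = generate_weather(
        config.n_days,
        config.start_day_of_year,
        seed=seed,
        config=config.weather,
        start_date=config.start_date,
    )
    person_rows = []
    stress_parts = []
    activity_parts = []
    traces: dict[str, np.ndarray] = {}
    for i in range(config.n_persons):
        pid = f"p{i:03d}"
        for attempt in range(config.max_redraws):
            rng = _rng(seed, _PERSON_STREAM, i, attempt)
            if drivers is not None:
                params = dominant_driver_params(
                    config, rng, pid, drivers[i % len(drivers)]
                )
            else:
                params = draw_person_params(config, rng, pid)
            stress, activity, tr = _generate_person(
                config, weather, params, rng, long_record=i < config.n_long_records
            )
            obs = stress["rating"].dropna()
            if len(obs) >= config.min_observed_ratings and obs.var() >= config.min_rating_variance:
                break
        else:
            raise ConfigError(
                f"could not draw a non-degenerate person after "
                f"{config.max_redraws} attempts (person index {i}); "
                "check the noise/effect configuration"
            )
        row = dataclasses.asdict(params)
        row["n_days"] = len(stress)
        row["n_observed"] = int(len(obs))
        row["redraws"] = attempt
        if drivers is not None:
            row["driver"] = drivers[i % len(drivers)]
        person_rows.append(row)
        stress_parts.append(stress)
        activity_parts.append(activity)
        traces[pid] = tr
    return Cohort(
        config=config,
        seed=seed,
        persons=pd.DataFrame(person_rows),
        weather=weather,
        stress=pd.concat(stress_parts, ignore_index=True),
        activity=pd.concat(activity_parts, ignore_index=True),
        traces=traces,
    )


def load_cohort_tables(indir) -> dict[str, pd.DataFrame]:
    """Read a written cohort directory back into frames (no minute traces)."""
    indir = Path(indir)
    out = {}
    for name in ("weather", "stress", "persons", "daily_activity"):
        path = indir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing cohort file: {path}")
        df = pd.read_csv(path)
        if "date" in df.columns:
            df["date"] = pd.to_datetime(df["date"]).dt.date
        out[name] = df
    return out
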