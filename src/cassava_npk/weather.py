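"""Daily weather drivers: reading, thermal time, light interception, synthesis.

Thermal time (TSUM, degC d) accumulates the daily effective temperature —
the mean of the daily extremes above a base temperature — from planting
onwards and drives phenology and the concentration lookups.  Intercepted
photosynthetically active radiation follows Beer's law on leaf area index,
with PAR taken as half of global radiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WeatherDay:
    """One day of driving data."""

    date: pd.Timestamp
    tmin: float               # degC
    tmax: float               # degC
    srad: float               # global radiation, MJ m-2 d-1
    rain: float               # mm d-1

    def __post_init__(self):
        if self.tmin > self.tmax:
            raise ValueError(f"{self.date.date()}: tmin {self.tmin} > tmax {self.tmax}")
        if self.srad < 0:
            raise ValueError(f"{self.date.date()}: negative radiation")
        if self.rain < 0:
            raise ValueError(f"{self.date.date()}: negative rain")


REQUIRED_COLUMNS = ("date", "tmin", "tmax", "srad", "rain")


def read_weather(path) -> list[WeatherDay]:
    """Read a daily weather CSV into a chronologically sorted, gap-free list.

    Required columns: date (ISO-8601), tmin, tmax, srad, rain.  Duplicate or
    missing dates and non-numeric cells are reported as errors.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"weather file missing column(s): {', '.join(missing)}")
    frame["date"] = pd.to_datetime(frame["date"])
    frame = frame.sort_values("date").reset_index(drop=True)
    dups = frame["date"][frame["date"].duplicated()]
    if not dups.empty:
        raise ValueError(f"duplicate weather date: {dups.iloc[0].date()}")
    deltas = frame["date"].diff().dropna()
    gaps = deltas[deltas != pd.Timedelta(days=1)]
    if not gaps.empty:
        where = frame["date"][gaps.index[0]].date()
        raise ValueError(f"weather date gap before {where}")
    for col in ("tmin", "tmax", "srad", "rain"):
        values = pd.to_numeric(frame[col], errors="coerce")
        if values.isna().any():
            bad = frame["date"][values.isna()].iloc[0].date()
            raise ValueError(f"non-numeric {col} value on {bad}")
        frame[col] = values
    return [WeatherDay(row.date, float(row.tmin), float(row.tmax),
                       float(row.srad), float(row.rain))
            for row in frame.itertuples(index=False)]


def write_weather(path, days) -> None:
    pd.DataFrame(
        {"date": [d.date.date().isoformat() for d in days],
         "tmin": [d.tmin for d in days],
         "tmax": [d.tmax for d in days],
         "srad": [d.srad for d in days],
         "rain": [d.rain for d in days]}
    ).to_csv(path, index=False)


def daily_thermal_increment(day: WeatherDay, base_temperature: float,
                            delt: float = 1.0) -> float:
    """Thermal-time increment: max(0, mean(tmin, tmax) - base) * DELT."""
    return max(0.0, 0.5 * (day.tmin + day.tmax) - base_temperature) * delt


def intercepted_par(day: WeatherDay, lai: float, k: float) -> float:
    """Beer's-law intercepted PAR: 0.5 * srad * (1 - exp(-k * LAI))."""
    if lai < 0:
        raise ValueError("LAI must be >= 0")
    return 0.5 * day.srad * (1.0 - math.exp(-k * lai))


# ---------------------------------------------------------------------------
# synthetic weather
# ---------------------------------------------------------------------------

PROFILES = ("wet", "dry-spell")


def generate_synthetic_weather(seed: int, n_days: int, climate_profile: str = "wet",
                               start: str = "2016-05-24") -> list[WeatherDay]:
    """Generate a reproducible humid-tropical weather series.

    Two profiles are offered.  ``"wet"`` emulates a season with abundant,
    well-distributed rainfall (~3,000 mm over 14 months, a short mild dry
    season) such that a deep-rooted crop experiences essentially no drought.
    ``"dry-spell"`` carries the same temperature and radiation climate but a
    pronounced mid-season drought: a contiguous window of >= 60 days, centred
    about seven months after planting, receives under 10% of the mean daily
    rain.  Identical ``seed`` and arguments give an identical series.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if climate_profile not in PROFILES:
        raise ValueError(f"unknown climate profile {climate_profile!r}; "
                         f"choose from {PROFILES}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_days)
    annual = np.cos(2.0 * np.pi * t / 365.0)  # phase 0 at planting (onset of rains)

    # temperatures: warm, small annual cycle, slightly warmer in the dry season
    tmin = 21.5 + 1.2 * annual + rng.normal(0.0, 0.8, n_days)
    tmax = tmin + 8.5 + 1.5 * annual + rng.normal(0.0, 1.0, n_days)
    tmax = np.maximum(tmax, tmin + 0.5)

    # radiation: 14-20 MJ m-2 d-1, higher under the drier (clearer) sky
    srad = 16.0 + 2.0 * annual + rng.normal(0.0, 2.0, n_days)
    srad = np.clip(srad, 8.0, 26.0)

    # rainfall: wet-season mean ~9 mm d-1 modulated by the annual cycle
    wet_prob = np.clip(0.62 + 0.30 * annual, 0.05, 0.95)
    mean_depth = np.clip(11.0 + 5.0 * annual, 1.0, None)
    raining = rng.random(n_days) < wet_prob
    rain = np.where(raining, rng.gamma(1.2, 1.0, n_days) * mean_depth / 1.2, 0.0)

    if climate_profile == "dry-spell":
        # deterministic 80-day drought centred ~7 months after planting
        lo, hi = 180, 260
        window = (t >= lo) & (t < hi)
        rain[window] *= 0.02

    dates = pd.date_range(start, periods=n_days, freq="D")
    return [WeatherDay(d, float(lo_), float(hi_), float(s), float(r))
            for d, lo_, hi_, s, r in zip(dates, tmin, tmax, srad, rain)]
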