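"""Collapse eligible home-days into the three analysis surfaces.

* **daily summaries** — one mean per outcome per home over the selected
  four-week weekday window, in hours/day (or percent for rooms used);
* **hour-to-hour profiles** — 24 values per outcome per home: the mean
  percentage of each clock hour spent in the outcome across selected days;
* **daily change over time** — per-home OLS slope of the daily value against
  calendar day index, plus the SD of the daily values, for homes monitored
  longer than 180 eligible days.

Because hourly metrics are window clips of the same interval sets as daily
metrics, the partition identity  sum_h profile(h)/100 * 1h  =  daily mean
holds exactly for every duration outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics_core import (
    ALL_OUTCOMES,
    DURATION_OUTCOMES,
    HomeIntervals,
    SECONDS_PER_HOUR,
    _day_bounds,
)

HOURS_PER_DAY = 24


def daily_summary(selected: pd.DataFrame, outcomes=ALL_OUTCOMES) -> pd.DataFrame:
    """Per-home arithmetic mean of each outcome over the selected days."""
    return selected.groupby("home_id")[list(outcomes)].mean()


def hourly_summary(
    home_intervals: dict[str, HomeIntervals],
    selected: pd.DataFrame,
    outcomes=DURATION_OUTCOMES,
) -> pd.DataFrame:
    """24-point hour-to-hour profiles per home and outcome.

    Hour ``h`` covers ``[h:00, h+1:00)`` local time.  Values are the mean
    fraction of that hour spent in the outcome across the selected days,
    reported as percent/hour.  Index: (home_id, outcome); columns: 0..23.
    """
    rows = []
    for home_id, days in selected.groupby("home_id", sort=True)["date"]:
        hi = home_intervals[home_id]
        acc = np.zeros((len(outcomes), HOURS_PER_DAY))
        for date in days:
            t0, _ = _day_bounds(date)
            for h in range(HOURS_PER_DAY):
                w0 = t0 + h * 3600
                rec = hi.window_metrics(w0, w0 + 3600)
                for i, outcome in enumerate(outcomes):
                    acc[i, h] += rec[outcome]
        acc /= len(days)
        for i, outcome in enumerate(outcomes):
            rows.append({"home_id": home_id, "outcome": outcome}
                        | {h: 100.0 * acc[i, h] for h in range(HOURS_PER_DAY)})
    out = pd.DataFrame(rows)
    return out.set_index(["home_id", "outcome"])


def home_trend(
    eligible: pd.DataFrame,
    outcomes=ALL_OUTCOMES,
    min_days: int = 180,
) -> pd.DataFrame:
    """Per-home slope and variability of each outcome's daily series.

    The slope is the OLS slope of the daily value against calendar day index
    counted from the home's first eligible day, so gaps advance the clock
    (change over time is calendar change).  Variability is the SD of the raw
    daily values.  Homes with <= ``min_days`` eligible days are dropped.
    Returns one row per (home_id, outcome) with columns slope (outcome units
    per day), variability and n_days.
    """
    rows = []
    for home_id, grp in eligible.groupby("home_id", sort=True):
        n_days = len(grp)
        if n_days <= min_days:
            continue
        day_index = (grp["date"] - grp["date"].min()).dt.days.to_numpy(dtype=float)
        x = day_index - day_index.mean()
        sxx = float(x @ x)
        for outcome in outcomes:
            y = grp[outcome].to_numpy(dtype=float)
            slope = float(x @ (y - y.mean())) / sxx
            rows.append(
                {
                    "home_id": home_id,
                    "outcome": outcome,
                    "slope": slope,
                    "variability": float(np.std(y, ddof=1)),
                    "n_days": n_days,
                }
            )
    return pd.DataFrame(rows, columns=["home_id", "outcome", "slope", "variability", "n_days"])


# --- reporting-unit conversions -------------------------------------------
# The internal unit for duration outcomes is hours/day, so a trend slope is
# hours/day per day.  Narrative units:


def slope_to_seconds_per_day(slope_hours_per_day: float) -> float:
    """Convert a trend slope from hours/day-per-day to seconds/day."""
    return slope_hours_per_day * SECONDS_PER_HOUR


def slope_to_minutes_per_year(slope_hours_per_day: float) -> float:
    """Convert a trend slope from hours/day-per-day to minutes/year."""
    return slope_hours_per_day * SECONDS_PER_HOUR * 365 / 60
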