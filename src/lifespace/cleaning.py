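"""Day-exclusion rules and home eligibility for the analysis surfaces.

A home-day enters analysis only if none of the following hold:

* the self-report week covering it had overnight visitors or the residents
  were away overnight (the whole 7-day reported week is excluded);
* one or more installed sensors were inactive that day (low battery etc.);
* the day falls after the COVID-19 restriction declaration for the home's
  site (2020-03-20 in Illinois for RUSH, 2020-03-23 in Oregon for OHSU/VA);
* the day falls after a move to a new home or a resident change;
* the day is within the home's first 14 calendar days of monitoring
  (burn-in against observation-effect behavior change);
* the day is a Saturday or Sunday (weekend patterns differ).

Two selection modes follow: ``four_week`` takes each home's first four weeks
of eligible weekdays (up to 20 days, interruptions ignored) and
``longitudinal`` takes all eligible days but requires more than 180 of them.
In both modes homes with under four weeks of eligible data are dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .sensor_io import parse_move_dates

logger = logging.getLogger(__name__)

#: Pandemic-restriction cutoffs per recruiting site; days *after* these dates
#: are excluded.
COVID_CUTOFFS = {
    "RUSH": pd.Timestamp("2020-03-20"),  # Illinois
    "OHSU": pd.Timestamp("2020-03-23"),  # Oregon
    "VA": pd.Timestamp("2020-03-23"),  # Oregon
}

BURN_IN_DAYS = 14
FOUR_WEEK_MAX_DAYS = 20  # weekdays in four weeks
MIN_ELIGIBLE_DAYS = 20  # "> 4 weeks of data" floor
LONGITUDINAL_MIN_DAYS = 180  # strictly more than this many eligible days

FLAG_COLUMNS = [
    "visitor_week",
    "away_week",
    "sensor_inactive",
    "post_covid",
    "post_move",
    "burn_in",
    "weekend",
]


def detect_sensor_outages(events: pd.DataFrame) -> pd.DataFrame:
    """Flag home-days on which an installed sensor was inactive.

    A motion sensor is considered installed in a home if it ever emits an
    event there; it is inactive on a calendar day if it emits nothing that
    day.  A day counts as an outage day when at least one installed motion
    sensor is silent (including fully silent days, which indicate a
    whole-system outage).  Door contacts are not health-checked this way: a
    door fires only at crossings, so a silent day is uninformative.
    Returns a frame with columns ``home_id, date, sensor_inactive``.
    """
    events = events[events["sensor_kind"] == "motion"]
    rows = []
    for home_id, grp in events.groupby("home_id", sort=True):
        sensors = grp["sensor_id"].unique()
        days = grp["timestamp"].dt.normalize()
        per_day = days.groupby([days, grp["sensor_id"]]).size().unstack(fill_value=0)
        per_day = per_day.reindex(columns=sensors, fill_value=0)
        all_days = pd.date_range(days.min(), days.max(), freq="D")
        per_day = per_day.reindex(all_days, fill_value=0)
        inactive = (per_day == 0).any(axis=1)
        for date, flag in inactive.items():
            rows.append({"home_id": home_id, "date": date, "sensor_inactive": bool(flag)})
    return pd.DataFrame(rows, columns=["home_id", "date", "sensor_inactive"])


def flag_days(
    day_records: pd.DataFrame,
    weekly_reports: pd.DataFrame,
    metadata: pd.DataFrame,
    outages: pd.DataFrame | None = None,
    *,
    burn_in_days: int = BURN_IN_DAYS,
    covid_cutoffs: dict | None = None,
) -> pd.DataFrame:
    """Attach exclusion flags and an ``eligible`` column to day records.

    A reported week covers the 7 days starting at its ``week_start``.  The
    burn-in window is each home's first 14 calendar days of day records.
    ``outages`` is the output of :func:`detect_sensor_outages` (or any frame
    with the same columns); if omitted, no outage flags are set.
    """
    out = day_records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.normalize()
    for col in FLAG_COLUMNS:
        out[col] = False

    missing_site = set(out["home_id"]) - set(metadata.index)
    if missing_site:
        raise ValueError(f"no metadata (site) for homes {sorted(missing_site)}")

    # visitor / away weeks
    for _, rep in weekly_reports.iterrows():
        if not (rep["overnight_visitors"] or rep["away_overnight"]):
            continue
        in_week = (
            (out["home_id"] == rep["home_id"])
            & (out["date"] >= rep["week_start"])
            & (out["date"] < rep["week_start"] + pd.Timedelta(days=7))
        )
        if rep["overnight_visitors"]:
            out.loc[in_week, "visitor_week"] = True
        if rep["away_overnight"]:
            out.loc[in_week, "away_week"] = True

    if outages is not None and len(outages):
        key = pd.MultiIndex.from_frame(out[["home_id", "date"]])
        omap = outages.set_index(["home_id", pd.to_datetime(outages["date"]).dt.normalize()])[
            "sensor_inactive"
        ]
        out["sensor_inactive"] = key.map(omap).fillna(False).to_numpy(dtype=bool)

    site = out["home_id"].map(metadata["site"])
    cutoff = site.map(covid_cutoffs or COVID_CUTOFFS)
    out["post_covid"] = out["date"] > cutoff

    for home_id, meta in metadata.iterrows():
        moves = parse_move_dates(meta.get("move_dates", ""))
        if moves:
            first_move = min(moves)
            sel = (out["home_id"] == home_id) & (out["date"] > first_move)
            out.loc[sel, "post_move"] = True

    first_day = out.groupby("home_id")["date"].transform("min")
    out["burn_in"] = out["date"] < first_day + pd.Timedelta(days=burn_in_days)

    out["weekend"] = out["date"].dt.dayofweek >= 5

    out["eligible"] = ~out[FLAG_COLUMNS].any(axis=1)
    return out


def eligibility_window(
    flagged: pd.DataFrame,
    mode: str,
    *,
    min_eligible_days: int = MIN_ELIGIBLE_DAYS,
    four_week_max_days: int = FOUR_WEEK_MAX_DAYS,
    longitudinal_min_days: int = LONGITUDINAL_MIN_DAYS,
) -> pd.DataFrame:
    """Select the analysis day set per home.

    ``four_week`` keeps each home's first :data:`FOUR_WEEK_MAX_DAYS` eligible
    weekdays, counting eligible days only (data-collection interruptions are
    ignored).  ``longitudinal`` keeps all eligible days but drops homes with
    <= 180 of them.  Homes with fewer than four weeks (20 days) of eligible
    data are dropped in both modes.
    """
    if mode not in {"four_week", "longitudinal"}:
        raise ValueError(f"unknown mode {mode!r}")
    eligible = flagged[flagged["eligible"]].sort_values(["home_id", "date"])
    kept, dropped = [], []
    for home_id, grp in eligible.groupby("home_id", sort=True):
        n = len(grp)
        if n < min_eligible_days:
            dropped.append((home_id, n, "under 4 weeks of eligible data"))
            continue
        if mode == "four_week":
            kept.append(grp.head(four_week_max_days))
        else:
            if n <= longitudinal_min_days:
                dropped.append((home_id, n, "<= 180 eligible days"))
                continue
            kept.append(grp)
    for home_id, n, reason in dropped:
        logger.info("dropping home %s (%d eligible days): %s", home_id, n, reason)
    if not kept:
        return eligible.iloc[0:0]
    out = pd.concat(kept, ignore_index=True)
    out.attrs["dropped_homes"] = {h: reason for h, _n, reason in dropped}
    return out


def remove_outliers(
    values: pd.Series, n_sd: float = 5.0
) -> tuple[pd.Series, pd.Index]:
    """Drop values deviating more than ``n_sd`` SDs from the mean.

    Single pass: mean and SD are computed once over all homes and not
    recomputed after removal, so the rule's removal count is well defined.
    Strict inequality — a value at exactly 5 SD is retained.  With zero
    variance nothing is removed.
    """
    values = values.dropna()
    if len(values) < 3:
        return values, values.index[:0]
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return values, values.index[:0]
    dev = (values - values.mean()).abs()
    removed = values.index[dev > n_sd * sd]
    if len(removed):
        logger.info("removed %d outliers beyond %.0f SD", len(removed), n_sd)
    return values.drop(removed), removed
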