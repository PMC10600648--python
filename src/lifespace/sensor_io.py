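"""Reading, validation and serialization of sensor event logs and study files.

The on-disk dialect is a flat state-change log: one CSV row per sensor
transition, which is the minimal faithful representation of what PIR motion
sensors and door contact sensors emit.  Three file kinds exist:

* **event log** — ``home_id,timestamp,sensor_id,sensor_kind,location,state``
  with ISO-8601 naive local timestamps at 1-second resolution.  ``state`` is
  1 for "motion detected" / "door open" and 0 for "motion no longer
  detected" / "door closed".
* **home metadata** — one row per home: resident counts, MCI-home status,
  demographic covariates, number of installed motion sensors (= rooms), the
  recruiting site, and optional move / resident-change dates.
* **weekly reports** — self-reported overnight visitors / away-overnight
  flags, one row per home-week.

All files are UTF-8 with LF line endings, so ``write(read(x))`` is
bit-identical for well-formed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of motion-sensor room labels.  ``bedroom2plus`` covers
#: every bedroom beyond the main bedroom; only ``bedroom1`` is reported as a
#: room-use outcome downstream.
MOTION_LOCATIONS = frozenset(
    {"livingroom", "kitchen", "bathroom", "bedroom1", "bedroom2plus", "other"}
)

SENSOR_KINDS = frozenset({"motion", "door"})

EVENT_COLUMNS = ["home_id", "timestamp", "sensor_id", "sensor_kind", "location", "state"]
METADATA_COLUMNS = [
    "home_id",
    "n_residents",
    "mci_home",
    "mean_age",
    "n_female",
    "n_male",
    "n_white",
    "n_other_ethnicity",
    "mean_education",
    "n_rooms",
    "site",
    "move_dates",
]
REPORT_COLUMNS = ["home_id", "week_start", "overnight_visitors", "away_overnight"]

SITES = frozenset({"OHSU", "VA", "RUSH"})


class FormatError(ValueError):
    """A file violates the declared dialect or an invariant of its type."""


@dataclass
class ValidationReport:
    """Outcome of validating/normalizing one event log."""

    n_rows: int = 0
    n_collapsed: int = 0  # repeated identical states dropped (PIR retrigger chatter)
    n_malformed: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.n_malformed == 0


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def normalize_events(events: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse repeated identical states within each sensor channel.

    PIR sensors can retrigger while a room is continuously active; a second
    ``1`` before any ``0`` carries no information and must not open a phantom
    interval.  Only the first occurrence of a run of identical states is
    kept.  Returns the normalized frame and the number of rows collapsed.
    """
    if events.empty:
        return events, 0
    same = (
        events["home_id"].eq(events["home_id"].shift())
        & events["sensor_id"].eq(events["sensor_id"].shift())
        & events["state"].eq(events["state"].shift())
    )
    n_collapsed = int(same.sum())
    if n_collapsed:
        events = events.loc[~same].reset_index(drop=True)
    return events, n_collapsed


def validate_events(
    events: pd.DataFrame, *, auto_sort: bool = False, path="<memory>"
) -> tuple[pd.DataFrame, ValidationReport]:
    """Enforce the event-log invariants; normalize what is normalizable.

    Sorting is by (sensor_id, timestamp) and stable, so identical-timestamp
    events from different sensors preserve input order.  Non-monotone
    timestamps within a sensor are fatal unless ``auto_sort`` is set.
    """
    report = ValidationReport(n_rows=len(events))
    _require_columns(events, EVENT_COLUMNS, path)

    events = events.copy()
    events["state"] = pd.to_numeric(events["state"], errors="coerce")
    malformed = events["state"].isna() | ~events["state"].isin([0, 1])
    ts = pd.to_datetime(events["timestamp"], format="ISO8601", errors="coerce")
    malformed |= ts.isna()
    if malformed.any():
        report.n_malformed = int(malformed.sum())
        report.warnings.append(f"dropped {report.n_malformed} malformed rows")
        logger.warning("%s: dropped %d malformed rows", path, report.n_malformed)
        events, ts = events.loc[~malformed], ts.loc[~malformed]
    events["timestamp"] = ts.dt.floor("s")
    events["state"] = events["state"].astype(np.int8)

    bad_kind = ~events["sensor_kind"].isin(SENSOR_KINDS)
    if bad_kind.any():
        raise FormatError(
            f"{path}: unknown sensor_kind values {sorted(events.loc[bad_kind, 'sensor_kind'].unique())}"
        )
    motion = events["sensor_kind"] == "motion"
    bad_loc = motion & ~events["location"].isin(MOTION_LOCATIONS)
    if bad_loc.any():
        raise FormatError(
            f"{path}: unknown motion locations "
            f"{sorted(events.loc[bad_loc, 'location'].unique())} "
            f"(closed vocabulary: {sorted(MOTION_LOCATIONS)})"
        )

    non_monotone = (
        events.groupby(["home_id", "sensor_id"], sort=False)["timestamp"]
        .diff()
        .dt.total_seconds()
        < 0
    )
    if non_monotone.any():
        if not auto_sort:
            raise FormatError(
                f"{path}: non-monotone timestamps within sensors "
                f"{sorted(events.loc[non_monotone, 'sensor_id'].unique())}; "
                "pass auto_sort=True to reorder"
            )
        report.warnings.append("auto-sorted non-monotone timestamps")
    events = events.sort_values(
        ["home_id", "sensor_id", "timestamp"], kind="stable"
    ).reset_index(drop=True)

    events, n_collapsed = normalize_events(events)
    report.n_collapsed = n_collapsed
    if n_collapsed:
        report.warnings.append(f"collapsed {n_collapsed} repeated identical states")
    return events, report


def read_events(path, *, auto_sort: bool = False) -> pd.DataFrame:
    """Read and validate an event log.

    Returns events sorted stably by (sensor_id, timestamp), with repeated
    identical states collapsed.  The :class:`ValidationReport` is attached as
    ``df.attrs["validation"]``.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, EVENT_COLUMNS, path)
    events, report = validate_events(raw[EVENT_COLUMNS], auto_sort=auto_sort, path=path)
    events.attrs["validation"] = report
    return events


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    _write_csv(out[EVENT_COLUMNS], path)


def read_home_metadata(path) -> pd.DataFrame:
    """Read per-home metadata; one row per home, indexed by ``home_id``.

    Checks the demographic accounting identities (females + males = residents,
    White + other = residents) and basic ranges.  ``move_dates`` is an
    optional ``;``-separated list of ISO dates after which data are excluded.
    """
    df = pd.read_csv(path, dtype={"home_id": str, "site": str, "move_dates": str})
    _require_columns(df, [c for c in METADATA_COLUMNS if c != "move_dates"], path)
    if "move_dates" not in df.columns:
        df["move_dates"] = ""
    df["move_dates"] = df["move_dates"].fillna("")
    if df["home_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate home_id rows")
    for col in ["n_residents", "n_female", "n_male", "n_white", "n_other_ethnicity", "n_rooms"]:
        df[col] = df[col].astype(int)
    df["mci_home"] = df["mci_home"].astype(bool)
    if not df["n_residents"].isin([1, 2]).all():
        raise FormatError(f"{path}: n_residents must be 1 or 2")
    if (df["n_female"] + df["n_male"] != df["n_residents"]).any():
        bad = df.loc[df["n_female"] + df["n_male"] != df["n_residents"], "home_id"].tolist()
        raise FormatError(f"{path}: n_female + n_male != n_residents for homes {bad}")
    if (df["n_white"] + df["n_other_ethnicity"] != df["n_residents"]).any():
        bad = df.loc[
            df["n_white"] + df["n_other_ethnicity"] != df["n_residents"], "home_id"
        ].tolist()
        raise FormatError(f"{path}: n_white + n_other_ethnicity != n_residents for homes {bad}")
    if (df["n_rooms"] < 1).any():
        raise FormatError(f"{path}: n_rooms must be >= 1")
    bad_site = ~df["site"].isin(SITES)
    if bad_site.any():
        raise FormatError(f"{path}: unknown site {sorted(df.loc[bad_site, 'site'].unique())}")
    return df.set_index("home_id", drop=False)


def write_home_metadata(meta: pd.DataFrame, path) -> None:
    _write_csv(meta.reset_index(drop=True)[METADATA_COLUMNS], path)


def parse_move_dates(value: str) -> list[pd.Timestamp]:
    """Parse the ``;``-separated move/resident-change date list."""
    if not value or (isinstance(value, float) and np.isnan(value)):
        return []
    return [pd.Timestamp(v) for v in str(value).split(";") if v]


def read_weekly_reports(path) -> pd.DataFrame:
    """Read weekly self-report logs (overnight visitors / away overnight)."""
    df = pd.read_csv(path, dtype={"home_id": str})
    _require_columns(df, REPORT_COLUMNS, path)
    df["week_start"] = pd.to_datetime(df["week_start"], format="%Y-%m-%d")
    for col in ["overnight_visitors", "away_overnight"]:
        df[col] = df[col].map(_parse_bool)
    if df.duplicated(["home_id", "week_start"]).any():
        dups = df.loc[df.duplicated(["home_id", "week_start"]), "home_id"].unique()
        raise FormatError(f"{path}: duplicate week_start for homes {sorted(dups)}")
    return df


def write_weekly_reports(reports: pd.DataFrame, path) -> None:
    out = reports.copy()
    out["week_start"] = out["week_start"].dt.strftime("%Y-%m-%d")
    for col in ["overnight_visitors", "away_overnight"]:
        out[col] = out[col].map({True: "true", False: "false"})
    _write_csv(out[REPORT_COLUMNS], path)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise FormatError(f"not a boolean: {value!r}")


def _write_csv(df: pd.DataFrame, path) -> None:
    # LF endings and UTF-8 regardless of platform, to keep round-trips exact.
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")
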