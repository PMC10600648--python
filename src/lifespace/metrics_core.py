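"""Certainty-based life-space metrics from PIR motion and door-contact streams.

PIR motion sensors report state changes, not presence: a ``1`` when motion
starts and a ``0`` when motion is no longer detected.  A stationary occupant
is invisible, and in 2-person homes motion in another room can come from the
other resident, so per-person tracking is impossible.  Three conditions can
nevertheless be read off the streams with certainty, and they define the four
metrics computed here:

* **room use** — a room is known in use from first motion detection until
  motion is no longer detected by that room's sensor.  A lower bound on true
  dwell time.
* **ILSA** (independent life-space activity) — time during which at least two
  distinct rooms are in use simultaneously, implying at least two active
  people in the home.
* **TOOH** (time out of home) — the span between a door-open, at least one
  door-close, and the next door-open during which no motion at all is
  detected inside: nobody was home.
* **percentage of rooms used** — rooms with any motion in a window divided by
  the number of installed motion sensors (one per room).

All interval work uses half-open ``[start, end)`` intervals in integer
seconds, so concatenation is well defined and zero-length events cannot
arise.  Every metric is exactly equal to a 1-second occupancy-grid
computation; the test suite asserts this against a brute-force oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sensor_io import MOTION_LOCATIONS

logger = logging.getLogger(__name__)

#: Rooms reported as room-use outcomes.  Homes with several bedrooms report
#: only the main bedroom; additional bedrooms (``bedroom2plus``) and ``other``
#: rooms still participate in ILSA and percentage-of-rooms-used, which are
#: home-wide certainty conditions.
REPORTED_ROOMS = ("livingroom", "kitchen", "bathroom", "bedroom1")

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400


def _to_seconds(ts: pd.Series) -> np.ndarray:
    return ts.astype("datetime64[s]").astype(np.int64).to_numpy()


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union a set of half-open intervals into sorted, disjoint form."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = intervals[np.argsort(intervals[:, 0], kind="stable")]
    starts, ends = iv[:, 0], iv[:, 1]
    # an interval opens a new block iff it starts after the running max end
    run_end = np.maximum.accumulate(ends)
    new_block = np.empty(len(iv), dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > run_end[:-1]
    block = np.cumsum(new_block) - 1
    out = np.empty((block[-1] + 1, 2), dtype=np.int64)
    out[:, 0] = starts[new_block]
    out[:, 1] = np.maximum.reduceat(ends, np.flatnonzero(new_block))
    return out


def clip_intervals(intervals: np.ndarray, t0: int, t1: int) -> np.ndarray:
    """Intersect sorted disjoint intervals with the window ``[t0, t1)``."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    s = np.clip(intervals[:, 0], t0, t1)
    e = np.clip(intervals[:, 1], t0, t1)
    keep = e > s
    return np.stack([s[keep], e[keep]], axis=1)


def total_seconds(intervals: np.ndarray, t0: int | None = None, t1: int | None = None) -> int:
    """Total measure of disjoint intervals, optionally clipped to a window."""
    if t0 is not None:
        intervals = clip_intervals(intervals, t0, t1)
    if len(intervals) == 0:
        return 0
    return int((intervals[:, 1] - intervals[:, 0]).sum())


def _pair_channel(times: np.ndarray, states: np.ndarray, span_end: int) -> np.ndarray:
    """Pair alternating 1/0 states of one sensor into use intervals.

    A leading 0 (no preceding 1) is dropped with a warning; a trailing 1 is
    closed at the end of the covered data span, since the sensor is known
    active at least until the last observation.
    """
    if len(times) == 0:
        return np.empty((0, 2), dtype=np.int64)
    if states[0] == 0:
        logger.warning("dropping motion-off event with no preceding motion-on")
        times, states = times[1:], states[1:]
        if len(times) == 0:
            return np.empty((0, 2), dtype=np.int64)
    starts = times[states == 1]
    ends = times[states == 0]
    if len(ends) < len(starts):  # trailing unmatched 1
        ends = np.append(ends, max(span_end, times[-1]))
    return np.stack([starts, ends], axis=1)


def events_to_use_intervals(
    events: pd.DataFrame, span_end: int | None = None
) -> dict[str, np.ndarray]:
    """Turn one home's motion events into per-location use intervals.

    Events must be normalized (alternating states per sensor).  Intervals
    from multiple sensors mapped to the same location are unioned; the result
    per location is merged, disjoint and sorted.
    """
    motion = events[events["sensor_kind"] == "motion"]
    if span_end is None:
        span_end = 0 if events.empty else int(_to_seconds(events["timestamp"]).max())
    by_loc: dict[str, list[np.ndarray]] = {}
    for (loc, _sensor), grp in motion.groupby(["location", "sensor_id"], sort=False):
        iv = _pair_channel(
            _to_seconds(grp["timestamp"]), grp["state"].to_numpy(), span_end
        )
        by_loc.setdefault(loc, []).append(iv)
    return {
        loc: merge_intervals(np.concatenate(parts)) for loc, parts in by_loc.items()
    }


def room_use_seconds(intervals: np.ndarray, t0: int, t1: int) -> int:
    """Total in-window use time for one room (intervals clipped to window)."""
    return total_seconds(intervals, t0, t1)


def multi_room_intervals(use_by_location: dict[str, np.ndarray]) -> np.ndarray:
    """Instants at which >= 2 distinct locations are simultaneously in use.

    Triple and higher overlaps are counted once: this is the measure of the
    union of pairwise intersections, computed by a boundary sweep over the
    number of simultaneously active locations.
    """
    locs = [iv for iv in use_by_location.values() if len(iv)]
    if len(locs) < 2:
        return np.empty((0, 2), dtype=np.int64)
    points = np.concatenate(
        [np.stack([iv[:, 0], np.ones(len(iv), dtype=np.int64)], axis=1) for iv in locs]
        + [np.stack([iv[:, 1], -np.ones(len(iv), dtype=np.int64)], axis=1) for iv in locs]
    )
    order = np.lexsort((points[:, 1], points[:, 0]))  # at ties, close before open
    t, delta = points[order, 0], points[order, 1]
    active = np.cumsum(delta)
    # segment [t[i], t[i+1]) has `active[i]` rooms in use
    seg_start, seg_end, n_active = t[:-1], t[1:], active[:-1]
    keep = (n_active >= 2) & (seg_end > seg_start)
    return merge_intervals(np.stack([seg_start[keep], seg_end[keep]], axis=1))


def ilsa_seconds(use_by_location: dict[str, np.ndarray], t0: int, t1: int) -> int:
    """Independent life-space activity within a window, in seconds."""
    return total_seconds(multi_room_intervals(use_by_location), t0, t1)


def out_of_home_intervals(
    door_times: np.ndarray,
    door_states: np.ndarray,
    motion_times: np.ndarray,
    *,
    min_episode_seconds: int = 0,
    strict_interior: bool = True,
) -> np.ndarray:
    """Episodes during which nobody was home, from the pooled door channel.

    All egress-door sensors are pooled into one "any door" stream.  An
    episode runs from a door-open at ``t1`` through at least one door-close
    to the next door-open at ``t2``; it counts as out-of-home only if no
    motion is detected strictly inside ``(t1, t2)``.  With
    ``strict_interior`` (the default) motion exactly at a boundary — the
    resident triggering a hall sensor while stepping out — does not void the
    episode.  ``min_episode_seconds`` optionally suppresses short door-ajar
    chatter (no floor by default).
    """
    opens = door_times[door_states == 1]
    out: list[tuple[int, int]] = []
    motion_times = np.sort(motion_times)
    for t1, t2 in zip(opens[:-1], opens[1:]):
        closes_between = door_times[
            (door_states == 0) & (door_times > t1) & (door_times < t2)
        ]
        if len(closes_between) == 0:
            continue
        if strict_interior:
            lo = np.searchsorted(motion_times, t1, side="right")
            hi = np.searchsorted(motion_times, t2, side="left")
        else:
            lo = np.searchsorted(motion_times, t1, side="left")
            hi = np.searchsorted(motion_times, t2, side="right")
        if hi > lo:  # motion inside the episode: somebody was home
            continue
        if t2 - t1 >= max(min_episode_seconds, 1):
            out.append((t1, t2))
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return merge_intervals(np.array(out, dtype=np.int64))


def tooh_seconds(
    door_events: pd.DataFrame,
    motion_events: pd.DataFrame,
    t0: int,
    t1: int,
    **kwargs,
) -> int:
    """Time out of home within a window, in seconds.

    Episodes spanning the window edge (e.g. midnight) contribute only their
    in-window part.
    """
    iv = out_of_home_intervals(
        _to_seconds(door_events["timestamp"]),
        door_events["state"].to_numpy(),
        _to_seconds(motion_events["timestamp"]),
        **kwargs,
    )
    return total_seconds(iv, t0, t1)


def pct_rooms_used(
    motion_events: pd.DataFrame, t0: int, t1: int, n_rooms: int
) -> float:
    """Percentage of rooms with any detected motion in the window.

    One motion sensor is installed per room, so rooms are counted as distinct
    motion sensors with at least one event in the window.
    """
    if n_rooms < 1:
        raise ValueError("n_rooms must be >= 1")
    times = _to_seconds(motion_events["timestamp"])
    in_win = (times >= t0) & (times < t1)
    n_used = motion_events.loc[in_win, "sensor_id"].nunique()
    return 100.0 * n_used / n_rooms


@dataclass
class HomeIntervals:
    """Precomputed interval sets for one home, over its full covered span.

    Day- and hour-level metrics are window clips of these sets, which makes
    the hourly/daily partition identity exact by construction.
    """

    home_id: str
    span: tuple[int, int]
    use_by_location: dict[str, np.ndarray]
    multi_room: np.ndarray
    out_of_home: np.ndarray
    motion_events: pd.DataFrame = field(repr=False)

    def window_metrics(self, t0: int, t1: int, n_rooms: int | None = None) -> dict[str, float]:
        """Metrics for the window [t0, t1); pass ``n_rooms`` to include
        ``pct_rooms_used`` (skipped when None)."""
        hours = (t1 - t0) / SECONDS_PER_HOUR
        rec: dict[str, float] = {
            "tooh": total_seconds(self.out_of_home, t0, t1) / SECONDS_PER_HOUR,
            "ilsa": total_seconds(self.multi_room, t0, t1) / SECONDS_PER_HOUR,
        }
        for room in REPORTED_ROOMS:
            iv = self.use_by_location.get(room, np.empty((0, 2), dtype=np.int64))
            rec[room] = room_use_seconds(iv, t0, t1) / SECONDS_PER_HOUR
        if n_rooms is not None:
            rec["pct_rooms_used"] = pct_rooms_used(self.motion_events, t0, t1, n_rooms)
        for key in ("tooh", "ilsa", *REPORTED_ROOMS):
            assert 0.0 <= rec[key] <= hours + 1e-9
        return rec


def compute_home_intervals(
    events: pd.DataFrame,
    home_id: str | None = None,
    *,
    min_episode_seconds: int = 0,
    strict_interior: bool = True,
) -> HomeIntervals:
    """Derive all interval sets for one home's validated event stream."""
    if home_id is not None:
        events = events[events["home_id"] == home_id]
    elif not events.empty:
        home_id = events["home_id"].iloc[0]
    times = _to_seconds(events["timestamp"]) if len(events) else np.empty(0, np.int64)
    span = (int(times.min()), int(times.max())) if len(times) else (0, 0)
    motion = events[events["sensor_kind"] == "motion"]
    door = events[events["sensor_kind"] == "door"].sort_values("timestamp", kind="stable")
    use = events_to_use_intervals(events, span_end=span[1])
    out = out_of_home_intervals(
        _to_seconds(door["timestamp"]),
        door["state"].to_numpy(),
        _to_seconds(motion["timestamp"]),
        min_episode_seconds=min_episode_seconds,
        strict_interior=strict_interior,
    )
    return HomeIntervals(
        home_id=home_id or "",
        span=span,
        use_by_location=use,
        multi_room=multi_room_intervals(use),
        out_of_home=out,
        motion_events=motion,
    )


def _day_bounds(date: pd.Timestamp) -> tuple[int, int]:
    d0 = pd.Timestamp(date).normalize()
    return (
        int(d0.to_datetime64().astype("datetime64[s]").astype(np.int64)),
        int((d0 + pd.Timedelta(days=1)).to_datetime64().astype("datetime64[s]").astype(np.int64)),
    )


def day_metrics(
    events: pd.DataFrame, date, n_rooms: int, home_id: str | None = None, **kwargs
) -> dict[str, float]:
    """All metrics for one home on one calendar day (local midnight window)."""
    hi = compute_home_intervals(events, home_id, **kwargs)
    t0, t1 = _day_bounds(date)
    rec = hi.window_metrics(t0, t1, n_rooms)
    rec["home_id"], rec["date"] = hi.home_id, pd.Timestamp(date).normalize()
    return rec


def daily_metrics_table(
    events: pd.DataFrame, metadata: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """One row of metrics per home per covered calendar day.

    Covered days run from the first to the last observed event of each home.
    Durations are hours/day; ``pct_rooms_used`` is a percentage.
    """
    rows = []
    for home_id, home_events in events.groupby("home_id", sort=True):
        n_rooms = int(metadata.loc[home_id, "n_rooms"])
        hi = compute_home_intervals(home_events, home_id, **kwargs)
        first = home_events["timestamp"].min().normalize()
        last = home_events["timestamp"].max().normalize()
        for date in pd.date_range(first, last, freq="D"):
            t0, t1 = _day_bounds(date)
            rec = hi.window_metrics(t0, t1, n_rooms)
            rec["home_id"], rec["date"] = home_id, date
            rows.append(rec)
    cols = ["home_id", "date", "tooh", "ilsa", *REPORTED_ROOMS, "pct_rooms_used"]
    return pd.DataFrame(rows, columns=cols)


#: Metric columns whose daily value is a duration in hours.
DURATION_OUTCOMES = ("tooh", "ilsa", *REPORTED_ROOMS)
ALL_OUTCOMES = (*DURATION_OUTCOMES, "pct_rooms_used")
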