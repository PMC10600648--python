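"""Independent brute-force oracles used to validate the interval algebra.

Everything here works on a 1-second occupancy grid built directly from the
raw event semantics, with none of the package's interval machinery, so a
bug in the implementation cannot hide in its own oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _sec(ts) -> np.ndarray:
    return pd.Series(ts).astype("datetime64[s]").astype(np.int64).to_numpy()


def grid_metrics(events: pd.DataFrame, t0: int, t1: int, n_rooms: int) -> dict:
    """All daily metrics recomputed on a per-second boolean grid.

    The trailing-1 convention matches the sensor semantics: a channel left
    on stays on until the end of the home's covered data span.
    """
    n = t1 - t0
    motion = events[events["sensor_kind"] == "motion"]
    door = events[events["sensor_kind"] == "door"]
    span_end = int(_sec(events["timestamp"]).max()) if len(events) else t1

    loc_active: dict[str, np.ndarray] = {}
    for (loc, _sid), grp in motion.groupby(["location", "sensor_id"]):
        grid = np.zeros(n, dtype=bool)
        times = _sec(grp["timestamp"])
        states = grp["state"].to_numpy()
        i = 0
        while i < len(times):
            if states[i] == 1:
                start = times[i]
                end = times[i + 1] if i + 1 < len(times) else span_end
                a, b = max(start, t0), min(end, t1)
                if b > a:
                    grid[a - t0 : b - t0] = True
                i += 2
            else:
                i += 1  # off with no preceding on: ignored
        loc_active[loc] = loc_active.get(loc, np.zeros(n, dtype=bool)) | grid

    active_counts = np.zeros(n, dtype=int)
    for grid in loc_active.values():
        active_counts += grid

    # TOOH by literal enumeration of open-close-open episodes
    door_sorted = door.sort_values("timestamp", kind="stable")
    dt = _sec(door_sorted["timestamp"])
    ds = door_sorted["state"].to_numpy()
    motion_times = np.sort(_sec(motion["timestamp"]))
    out_grid = np.zeros(n, dtype=bool)
    opens = dt[ds == 1]
    for a, b in zip(opens[:-1], opens[1:]):
        has_close = np.any((dt > a) & (dt < b) & (ds == 0))
        interior_motion = np.any((motion_times > a) & (motion_times < b))
        if has_close and not interior_motion and b > a:
            lo, hi = max(a, t0), min(b, t1)
            if hi > lo:
                out_grid[lo - t0 : hi - t0] = True

    in_window = (_sec(motion["timestamp"]) >= t0) & (_sec(motion["timestamp"]) < t1)
    rec = {
        "tooh": out_grid.sum() / 3600.0,
        "ilsa": (active_counts >= 2).sum() / 3600.0,
        "pct_rooms_used": 100.0 * motion.loc[in_window, "sensor_id"].nunique() / n_rooms,
    }
    for loc, grid in loc_active.items():
        rec[loc] = grid.sum() / 3600.0
    return rec


def random_event_stream(rng: np.random.Generator, day: str = "2021-03-02") -> pd.DataFrame:
    """A random but well-formed single-home event stream within one day."""
    d0 = pd.Timestamp(day)
    rows = []
    locations = rng.permutation(
        ["livingroom", "kitchen", "bathroom", "bedroom1", "bedroom2plus", "other"]
    )[: rng.integers(1, 6)]
    for i, loc in enumerate(locations):
        for sensor_rep in range(rng.integers(1, 3)):  # some rooms have 2 sensors
            n_events = int(rng.integers(0, 20))
            times = np.sort(rng.choice(86400, size=n_events, replace=False))
            for j, t in enumerate(times):
                rows.append(
                    {
                        "home_id": "h",
                        "timestamp": d0 + pd.Timedelta(seconds=int(t)),
                        "sensor_id": f"m{i}_{sensor_rep}",
                        "sensor_kind": "motion",
                        "location": loc,
                        "state": (j + 1) % 2,  # start with 1, alternate
                    }
                )
    n_door = int(rng.integers(0, 16))
    times = np.sort(rng.choice(86400, size=n_door, replace=False))
    for j, t in enumerate(times):
        rows.append(
            {
                "home_id": "h",
                "timestamp": d0 + pd.Timedelta(seconds=int(t)),
                "sensor_id": "d0",
                "sensor_kind": "door",
                "location": "frontdoor",
                "state": (j + 1) % 2,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["home_id", "timestamp", "sensor_id", "sensor_kind", "location", "state"],
    )
    return df.sort_values(["sensor_id", "timestamp"], kind="stable").reset_index(drop=True)


def physics_violations(cohort, daily: pd.DataFrame, reported_rooms) -> int:
    """Count violations of the certainty bounds against simulator truth.

    Days with an injected sensor outage are skipped: losing motion events
    can only shrink room use and ILSA but may fabricate out-of-home time,
    which is exactly why such days are excluded from analysis.
    """
    viol = 0
    for home_id, gt in cohort.truth.items():
        m = daily[daily["home_id"] == home_id].merge(gt.daily, on=["home_id", "date"])
        ok = ~m["outage"]
        viol += int((m.loc[ok, "tooh"] > m.loc[ok, "true_all_out"] + 1e-9).sum())
        viol += int((m.loc[ok, "ilsa"] > m.loc[ok, "true_multi_room"] + 1e-9).sum())
        for room in reported_rooms:
            viol += int((m.loc[ok, room] > m.loc[ok, f"true_{room}"] + 1e-9).sum())
    return viol
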