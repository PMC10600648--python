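"""Agent-based simulator of household routines with sensor-level ground truth.

The original cohort's raw sensor data are not publicly deposited, so every
pipeline stage is validated against this simulator instead: it moves one or
two residents (plus optional visitors and pets) through the rooms of a home
according to semi-Markov daily routines and emits exactly the event streams
the hardware would produce, together with the true occupancy it derived them
from.

Sensor physics encoded here:

* PIR sensors fire only while a person *moves* in a room.  Each room-dwell
  is a sequence of motion bouts separated by stationary spells; a ``1`` is
  emitted when a bout starts and a ``0`` when no motion has been seen for
  the PIR timeout (default 10 s).  Overlapping bouts from several occupants
  of the same room merge into one sensor episode, as a real detector would.
* A sleeping resident is stationary: bedrooms are silent overnight except
  for going-to-bed motion, so sensed bedroom use is far below true dwell.
* Door contacts emit open/close cycles at every exit and entry.

Group structure follows the study conditions: 2-person homes have
structurally lower time out of home (both residents must leave), higher
independent life-space activity (two residents co-using rooms) and more
night-time kitchen/living-room activity; MCI effects differ by household
type (fewer daytime visitors in 1-person MCI homes, more co-activity and
night kitchen use in 2-person MCI homes) and are tunable through the
scenario's effect parameters.

All randomness flows from the scenario seed through per-home substreams, so
the same scenario yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics_core import (
    REPORTED_ROOMS,
    SECONDS_PER_DAY,
    SECONDS_PER_HOUR,
    clip_intervals,
    merge_intervals,
    multi_room_intervals,
    total_seconds,
)

ARMS = ("1p_nomci", "1p_mci", "2p_nomci", "2p_mci")

H = int(SECONDS_PER_HOUR)
MIN = 60


@dataclass
class SimScenario:
    """Simulator configuration; defaults define the study conditions."""

    n_homes: dict = field(
        default_factory=lambda: {a: 12 for a in ARMS}
    )
    n_days: int = 70
    start_date: str = "2019-01-07"  # a Monday, pre-pandemic
    seed: int = 0

    # sensor model
    pir_timeout_s: int = 10  # seconds of stillness before a 0 is emitted
    door_latency_s: int = 5  # open -> close while passing through
    outage_prob: float = 0.003  # per sensor-day; events silently lost

    # resident routine (times in hours of day / events per day)
    wake_mean_h: float = 7.0
    wake_sd_h: float = 0.5
    sleep_mean_h: float = 22.5
    sleep_sd_h: float = 0.5
    outing_rate_per_day: float = 1.2
    outing_duration_mean_s: float = 5400.0
    outing_duration_sd_log: float = 0.5
    bathroom_visits_per_day: float = 3.0
    wander_dwell_mean_s: float = 1500.0
    wander_dwell_sd_log: float = 0.6

    # social / household structure
    visitor_rate_1p: float = 0.35  # daytime visitors per day, 1-person homes
    visitor_rate_2p: float = 0.10
    joint_outing_prob: float = 0.55  # 2-person homes: both residents leave
    coactivity_rate_2p: float = 1.5  # forced different-room sessions per day
    night_kitchen_prob_1p: float = 0.05  # per night
    night_kitchen_prob_2p: float = 0.25
    night_bathroom_prob: float = 0.3

    # weekly self-report processes
    overnight_visitor_week_prob: float = 0.04
    away_week_prob: float = 0.03

    # MCI effect profile (multiplicative deltas; 1.0 = no effect)
    mci_visitor_factor_1p: float = 0.4  # fewer visitors -> lower ILSA (1p)
    mci_outing_factor_1p: float = 1.3  # more midday outings (1p)
    mci_outing_factor_2p: float = 0.7  # couple leaves less (2p)
    mci_coactivity_factor_2p: float = 1.6  # more co-activity -> higher ILSA
    mci_night_kitchen_factor_2p: float = 1.8

    # pets: optional noise agents, off by default
    pet_home_prob: float = 0.0
    pet_bout_rate_per_hour: float = 2.0

    def null(self) -> "SimScenario":
        """A copy with every arm-level effect switched off (for type-I
        error studies): MCI deltas neutral and household structure evened
        out as far as the 1-vs-2-person design permits."""
        return replace(
            self,
            mci_visitor_factor_1p=1.0,
            mci_outing_factor_1p=1.0,
            mci_outing_factor_2p=1.0,
            mci_coactivity_factor_2p=1.0,
            mci_night_kitchen_factor_2p=1.0,
        )


@dataclass
class GroundTruth:
    """True occupancy behind one home's emitted events."""

    home_id: str
    #: agent -> list of (room, start_s, end_s) dwell segments (absolute epoch
    #: seconds); one agent's segments partition its at-home time
    segments: dict
    #: agent -> (n, 2) out-of-home intervals (residents) or presence gaps
    out_intervals: dict
    #: agent -> (n, 2) at-home presence intervals
    presence: dict
    #: per-day truth: true all-out hours, true >=2-room co-occupancy hours,
    #: true per-room dwell hours, and whether a sensor outage was injected
    daily: pd.DataFrame


def arm_of(meta_row: pd.Series) -> str:
    return ("2p" if meta_row["n_residents"] == 2 else "1p") + (
        "_mci" if meta_row["mci_home"] else "_nomci"
    )


# ---------------------------------------------------------------------------
# per-home simulation


def _rooms_for_home(n_residents: int, n_rooms: int) -> list[str]:
    rooms = ["livingroom", "kitchen", "bathroom", "bedroom1"]
    if n_residents == 2 and n_rooms >= 5:
        rooms.append("bedroom2plus")
    rooms += [f"other{i + 1}" for i in range(n_rooms - len(rooms))]
    return rooms[:n_rooms]


def _room_location(room: str) -> str:
    return "other" if room.startswith("other") else room


def _lognormal(rng, mean: float, sd_log: float, lo: float, hi: float) -> float:
    mu = np.log(mean) - sd_log**2 / 2
    return float(np.clip(rng.lognormal(mu, sd_log), lo, hi))


def _schedule_slots(rng, n: int, window: tuple[int, int], dur_fn, margin: int):
    """Greedily place n non-overlapping (start, end) slots in a window."""
    lo, hi = window
    slots: list[tuple[int, int]] = []
    starts = np.sort(rng.integers(lo, max(hi, lo + 1), size=n))
    for s in starts:
        d = int(dur_fn())
        e = min(s + d, hi)
        if e - s < 15 * MIN:
            continue
        if all(e + margin <= a or b + margin <= s for a, b in slots):
            slots.append((int(s), int(e)))
    return sorted(slots)


class _HomeSimulator:
    def __init__(self, scenario: SimScenario, home_id: str, meta: pd.Series, rng):
        self.sc = scenario
        self.home_id = home_id
        self.meta = meta
        self.rng = rng
        self.arm = arm_of(meta)
        self.two_p = meta["n_residents"] == 2
        self.mci = bool(meta["mci_home"])
        self.rooms = _rooms_for_home(meta["n_residents"], int(meta["n_rooms"]))
        self.extra_rooms = [r for r in self.rooms if r not in REPORTED_ROOMS]
        self.t0 = int(
            pd.Timestamp(scenario.start_date).to_datetime64().astype("datetime64[s]").astype(np.int64)
        )
        self.residents = [f"r{i}" for i in range(meta["n_residents"])]
        self.segments: dict[str, list] = {a: [] for a in self.residents}
        self.out: dict[str, list] = {a: [] for a in self.residents}
        self.door_cycles: list[int] = []  # open times; close = open + latency
        self.outage_days: set[tuple[str, int]] = set()
        self._effective_rates()

    def _effective_rates(self):
        sc = self.sc
        if self.two_p:
            self.outing_rate = sc.outing_rate_per_day * (
                sc.mci_outing_factor_2p if self.mci else 1.0
            )
            self.visitor_rate = sc.visitor_rate_2p
            self.coactivity_rate = sc.coactivity_rate_2p * (
                sc.mci_coactivity_factor_2p if self.mci else 1.0
            )
            self.night_kitchen_prob = sc.night_kitchen_prob_2p * (
                sc.mci_night_kitchen_factor_2p if self.mci else 1.0
            )
        else:
            self.outing_rate = sc.outing_rate_per_day * (
                sc.mci_outing_factor_1p if self.mci else 1.0
            )
            self.visitor_rate = sc.visitor_rate_1p * (
                sc.mci_visitor_factor_1p if self.mci else 1.0
            )
            self.coactivity_rate = 0.0
            self.night_kitchen_prob = sc.night_kitchen_prob_1p

    # -- one day ----------------------------------------------------------
    def simulate_day(self, day: int, visitor_week: bool):
        sc, rng = self.sc, self.rng
        d0 = self.t0 + day * SECONDS_PER_DAY
        d1 = d0 + SECONDS_PER_DAY
        wake = {}
        sleep = {}
        for a in self.residents:
            wake[a] = d0 + int(
                np.clip(rng.normal(sc.wake_mean_h, sc.wake_sd_h), 5.0, 9.5) * H
            )
            sleep[a] = d0 + int(
                np.clip(rng.normal(sc.sleep_mean_h, sc.sleep_sd_h), 20.5, 23.5) * H
            )
        window = (max(wake.values()) + 30 * MIN, min(sleep.values()) - 30 * MIN)

        # home-level outing slots (shared door; never overlapping)
        n_out = rng.poisson(self.outing_rate)
        outings = _schedule_slots(
            rng,
            n_out,
            window,
            lambda: _lognormal(
                rng, sc.outing_duration_mean_s, sc.outing_duration_sd_log,
                20 * MIN, 4 * H,
            ),
            margin=15 * MIN,
        )
        assigned = []  # (start, end, participants)
        for s, e in outings:
            if self.two_p and rng.random() >= sc.joint_outing_prob:
                assigned.append((s, e, [self.residents[rng.integers(2)]]))
            else:
                assigned.append((s, e, list(self.residents)))
        busy = [(s, e) for s, e, _ in assigned]

        # co-activity sessions: residents deliberately in different rooms
        coactivity = []
        if self.two_p:
            for s, e in _schedule_slots(
                rng, rng.poisson(self.coactivity_rate), window,
                lambda: rng.integers(20 * MIN, 40 * MIN), margin=5 * MIN,
            ):
                if all(e <= a or b <= s for a, b in busy):
                    pair = (
                        ("kitchen", "livingroom")
                        if rng.random() < 0.5
                        else ("livingroom", "kitchen")
                    )
                    coactivity.append((s, e, pair))
                    busy.append((s, e))

        # daytime visitor (at most one per day, only while a resident is home)
        visitor = None
        want_visitor = visitor_week or rng.random() < self.visitor_rate
        if want_visitor:
            lo = max(d0 + 10 * H, window[0])
            hi = min(d0 + 16 * H, window[1] - 30 * MIN)
            if hi > lo:
                vs = int(rng.integers(lo, hi))
                ve = min(vs + int(rng.integers(1 * H, 2 * H)), window[1])
                if all(ve + 10 * MIN <= a or b + 10 * MIN <= vs for a, b in busy):
                    visitor = (vs, ve)

        for i, a in enumerate(self.residents):
            self._resident_day(
                a, i, d0, d1, wake[a], sleep[a], assigned, coactivity,
                visitor if i == 0 else None, rng,
            )

        # door cycles for outings (one shared cycle per slot) and visitor
        for s, e, _members in assigned:
            self.door_cycles += [s, e]
        if visitor is not None:
            vs, ve = visitor
            self.door_cycles += [vs, ve]
            vid = f"v{day}"
            room = "livingroom" if rng.random() < 0.7 else "kitchen"
            self.segments[vid] = [(room, vs, ve, False, True)]
            self.out[vid] = []

    def _resident_day(
        self, agent, idx, d0, d1, wake, sleep, outings, coactivity, visitor, rng
    ):
        sc = self.sc
        # (start, end, room, asleep, busy); busy dwells are sustained-motion
        # activities (cooking, chores, hosting) with a high PIR duty cycle
        blocks: list[tuple[int, int, str, bool, bool]] = []

        my_out = [(s, e) for s, e, members in outings if agent in members]
        for s, e in my_out:
            self.out[agent].append((s, e))

        def free(s, e):
            return all(e <= a or b <= s for a, b in my_out) and all(
                e <= b[0] or b[1] <= s for b in [(x, y) for x, y, *_ in blocks]
            )

        # anchored blocks, placed in priority order
        for s, e, pair in coactivity:
            if free(s, e):
                blocks.append((s, e, pair[idx], False, True))
        # hosting a daytime visitor: the resident makes coffee in the kitchen
        if visitor is not None:
            vs, ve = visitor
            he = min(vs + 20 * MIN, ve)
            if free(vs, he):
                blocks.append((vs, he, "kitchen", False, True))
        # morning chain: bedroom -> bathroom -> kitchen (breakfast)
        chain = [("bedroom1", 5 * MIN), ("bathroom", 8 * MIN), ("kitchen", 25 * MIN)]
        t = wake
        for room, dur in chain:
            if free(t, t + dur):
                blocks.append((t, t + dur, room, False, room == "kitchen"))
            t += dur
        # lunch and dinner (cooking: sustained motion)
        for center_h, dur in ((12.6, 25 * MIN), (18.2, 35 * MIN)):
            s = d0 + int((center_h + rng.normal(0, 0.3)) * H)
            if s + dur < sleep and free(s, s + dur):
                blocks.append((s, s + dur, "kitchen", False, True))
        # scattered bathroom visits
        for _ in range(rng.poisson(sc.bathroom_visits_per_day)):
            s = int(rng.integers(wake + H, sleep - 10 * MIN))
            if free(s, s + 4 * MIN):
                blocks.append((s, s + 4 * MIN, "bathroom", False, False))

        # night structure: asleep in the main bedroom, with optional
        # excursions (kitchen snack, bathroom trip)
        night_excursions = []
        if rng.random() < self.night_kitchen_prob:
            s = d0 + int(rng.uniform(1.0, 4.0) * H)
            night_excursions.append((s, s + 12 * MIN, "kitchen"))
        if rng.random() < sc.night_bathroom_prob:
            s = d0 + int(rng.uniform(0.5, 5.0) * H)
            if all(e0 <= a or b <= s for a, b, _ in night_excursions for e0 in [s + 4 * MIN]):
                night_excursions.append((s, s + 4 * MIN, "bathroom"))
        night_excursions.sort()
        cursor = d0
        for s, e, room in night_excursions:
            s, e = max(s, cursor), min(e, wake)
            if e <= s:
                continue
            if s > cursor:
                blocks.append((cursor, s, "bedroom1", True, False))
            blocks.append((s, e, room, False, False))
            cursor = e
        if wake > cursor:
            blocks.append((cursor, wake, "bedroom1", True, False))
        blocks.append((sleep, d1, "bedroom1", True, False))

        # fill the remaining awake time with semi-Markov wandering,
        # visiting every not-yet-seen room first so each sensor fires daily
        occupied = sorted(
            [(s, e) for s, e, *_ in blocks] + my_out
        )
        visited = {room for _s, _e, room, asleep, _busy in blocks if not asleep}
        pending = [r for r in self.rooms if r not in visited]
        fill_blocks = []
        cursor = wake
        prev_room = "bedroom1"
        for s, e in occupied + [(d1, d1)]:
            while cursor < min(s, sleep) - MIN:
                gap_end = min(s, sleep)
                if pending:
                    room = pending.pop(0)
                    dur = int(rng.integers(2 * MIN, 5 * MIN))
                else:
                    room = self._next_room(prev_room, rng)
                    dur = int(
                        _lognormal(
                            rng, sc.wander_dwell_mean_s, sc.wander_dwell_sd_log,
                            2 * MIN, 2 * H,
                        )
                    )
                end = min(cursor + dur, gap_end)
                fill_blocks.append((cursor, end, room, False, False))
                prev_room = room
                cursor = end
            cursor = max(cursor, e)
            if cursor >= sleep:
                break

        day_blocks = sorted(blocks + fill_blocks)
        self.segments[agent] += [
            (room, s, e, asleep, busy)
            for s, e, room, asleep, busy in day_blocks
            if e > s
        ]

    def _next_room(self, prev: str, rng) -> str:
        weights = {"livingroom": 0.42, "kitchen": 0.12, "bedroom1": 0.06, "bathroom": 0.05}
        extra_w = 0.35 / max(len(self.extra_rooms), 1)
        for r in self.extra_rooms:
            weights[r] = extra_w
        rooms = [r for r in self.rooms if r != prev]
        w = np.array([weights.get(r, 0.05) for r in rooms])
        return rooms[rng.choice(len(rooms), p=w / w.sum())]

    # -- sensors -----------------------------------------------------------
    def emit_events(self) -> pd.DataFrame:
        sc, rng = self.sc, self.rng
        timeout = sc.pir_timeout_s
        bouts_by_room: dict[str, list[tuple[int, int]]] = {r: [] for r in self.rooms}
        for agent, segs in self.segments.items():
            for seg in segs:
                room, s, e = seg[0], seg[1], seg[2]
                asleep = seg[3] if len(seg) > 3 else False
                busy = seg[4] if len(seg) > 4 else False
                if room not in bouts_by_room:
                    continue
                if asleep:
                    # going-to-bed motion only, and only when the spell
                    # starts with the resident actually entering the room
                    if (s - self.t0) % SECONDS_PER_DAY != 0 and e - s > timeout + MIN:
                        bouts_by_room[room].append((s, min(s + 45, e - timeout)))
                    continue
                bouts_by_room[room] += self._bouts(s, e, rng, busy=busy)
        rows = []
        for room, bouts in bouts_by_room.items():
            if not bouts:
                continue
            iv = np.array(bouts, dtype=np.int64)
            iv[:, 1] += timeout  # 0 fires a timeout after the last motion
            for a, b in merge_intervals(iv):
                if (b - self.t0) % SECONDS_PER_DAY == 0:
                    b -= 1  # keep both events of a pair on the same day
                rows.append((a, f"m_{room}", "motion", _room_location(room), 1))
                rows.append((b, f"m_{room}", "motion", _room_location(room), 0))
        for t in sorted(self.door_cycles):
            rows.append((t, "d_front", "door", "frontdoor", 1))
            rows.append((t + sc.door_latency_s, "d_front", "door", "frontdoor", 0))
        events = pd.DataFrame(
            rows, columns=["t", "sensor_id", "sensor_kind", "location", "state"]
        ).sort_values(["sensor_id", "t"], kind="stable")

        # sensor outages: a motion sensor silently loses a whole day of
        # events (door-contact outages leave no detectable footprint, since
        # a silent door day is normal)
        sensors = [s for s in events["sensor_id"].unique() if s.startswith("m_")]
        day_idx = (events["t"] - self.t0) // SECONDS_PER_DAY
        drop = pd.Series(False, index=events.index)
        for sensor in sensors:
            bad_days = np.flatnonzero(rng.random(self.sc.n_days) < sc.outage_prob)
            for d in bad_days:
                self.outage_days.add((sensor, int(d)))
                drop |= (events["sensor_id"] == sensor) & (day_idx == d)
        events = events[~drop].reset_index(drop=True)

        events["home_id"] = self.home_id
        events["timestamp"] = pd.to_datetime(events["t"], unit="s")
        return events[
            ["home_id", "timestamp", "sensor_id", "sensor_kind", "location", "state"]
        ]

    def _bouts(self, s: int, e: int, rng, busy: bool = False) -> list[tuple[int, int]]:
        """Motion bouts within an awake dwell [s, e).

        Bouts never extend past ``e - timeout`` so the sensor's delayed 0
        still falls inside the true dwell, and the stationary gap between
        bouts stays under ~9 minutes: an awake resident is never invisible
        for long.
        """
        timeout = self.sc.pir_timeout_s
        lim = e - timeout
        bouts = []
        t = s
        while t < lim:
            b = min(t + int(rng.integers(20, 90)), lim)
            if b > t:
                bouts.append((t, b))
            still = rng.integers(10, 30) if busy else rng.integers(20, 2 * MIN)
            t = b + timeout + int(still)
        if not bouts and lim > s:
            bouts.append((s, lim))
        return bouts

    # -- ground truth ------------------------------------------------------
    def ground_truth(self) -> GroundTruth:
        span = (self.t0, self.t0 + self.sc.n_days * SECONDS_PER_DAY)
        presence = {}
        out_iv = {}
        for agent, segs in self.segments.items():
            if agent.startswith("r"):
                o = (
                    merge_intervals(np.array(self.out[agent], dtype=np.int64))
                    if self.out[agent]
                    else np.empty((0, 2), dtype=np.int64)
                )
                out_iv[agent] = o
                presence[agent] = _complement(o, *span)
            else:  # visitors are present exactly during their segments
                iv = np.array([(s, e) for _r, s, e, *_ in segs], dtype=np.int64)
                presence[agent] = merge_intervals(iv)
                out_iv[agent] = np.empty((0, 2), dtype=np.int64)

        room_occ: dict[str, list] = {}
        for segs in self.segments.values():
            for seg in segs:
                room_occ.setdefault(seg[0], []).append((seg[1], seg[2]))
        room_occ_iv = {
            r: merge_intervals(np.array(v, dtype=np.int64)) for r, v in room_occ.items()
        }
        anybody = merge_intervals(np.concatenate(list(presence.values())))
        all_out = _complement(anybody, *span)
        coocc = multi_room_intervals(room_occ_iv)

        outage_day_idx = {d for _s, d in self.outage_days}
        rows = []
        for day in range(self.sc.n_days):
            t0 = self.t0 + day * SECONDS_PER_DAY
            t1 = t0 + SECONDS_PER_DAY
            rec = {
                "home_id": self.home_id,
                "date": pd.Timestamp(self.sc.start_date) + pd.Timedelta(days=day),
                "true_all_out": total_seconds(all_out, t0, t1) / SECONDS_PER_HOUR,
                "true_multi_room": total_seconds(coocc, t0, t1) / SECONDS_PER_HOUR,
                "outage": day in outage_day_idx,
            }
            for room in REPORTED_ROOMS:
                iv = room_occ_iv.get(room, np.empty((0, 2), dtype=np.int64))
                rec[f"true_{room}"] = total_seconds(iv, t0, t1) / SECONDS_PER_HOUR
            rows.append(rec)
        return GroundTruth(
            home_id=self.home_id,
            segments={
                a: [(r, s, e) for r, s, e, *_ in segs]
                for a, segs in self.segments.items()
            },
            out_intervals=out_iv,
            presence=presence,
            daily=pd.DataFrame(rows),
        )


def _complement(intervals: np.ndarray, t0: int, t1: int) -> np.ndarray:
    iv = clip_intervals(intervals, t0, t1)
    edges = [t0] + list(iv.ravel()) + [t1]
    out = [
        (edges[i], edges[i + 1])
        for i in range(0, len(edges), 2)
        if edges[i + 1] > edges[i]
    ]
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def simulate_home(
    scenario: SimScenario, home_id: str, meta: pd.Series, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one home: validated events, weekly reports, ground truth."""
    rng = np.random.default_rng(seed)
    sim = _HomeSimulator(scenario, home_id, meta, rng)

    n_weeks = int(np.ceil(scenario.n_days / 7))
    visitor_weeks = rng.random(n_weeks) < scenario.overnight_visitor_week_prob
    away_weeks = rng.random(n_weeks) < scenario.away_week_prob
    for day in range(scenario.n_days):
        sim.simulate_day(day, visitor_week=bool(visitor_weeks[day // 7]))
    events = sim.emit_events()
    start = pd.Timestamp(scenario.start_date)
    reports = pd.DataFrame(
        {
            "home_id": home_id,
            "week_start": [start + pd.Timedelta(days=7 * w) for w in range(n_weeks)],
            "overnight_visitors": visitor_weeks,
            "away_overnight": away_weeks,
        }
    )
    return events, reports, sim.ground_truth()


@dataclass
class SimulatedCohort:
    scenario: SimScenario
    events: pd.DataFrame
    metadata: pd.DataFrame
    reports: pd.DataFrame
    truth: dict[str, GroundTruth]


#: Table-1-style demographic draws per arm: (age mean, age sd, rooms mean)
_ARM_DEMOGRAPHICS = {
    "1p_nomci": (74.0, 6.0, 6.0),
    "1p_mci": (72.0, 6.0, 5.0),
    "2p_nomci": (70.0, 4.0, 10.0),
    "2p_mci": (74.0, 7.0, 10.0),
}


def make_metadata(scenario: SimScenario) -> pd.DataFrame:
    """Draw per-home metadata mirroring the four-arm cohort structure."""
    rng = np.random.default_rng([scenario.seed, 7919])
    sites = ["OHSU", "VA", "RUSH"]
    rows = []
    i = 0
    for arm in ARMS:
        two_p = arm.startswith("2p")
        n_res = 2 if two_p else 1
        age_mu, age_sd, rooms_mu = _ARM_DEMOGRAPHICS[arm]
        for _ in range(scenario.n_homes.get(arm, 0)):
            if two_p:
                n_female = 2 if rng.random() < 0.04 else 1
                n_white = int(rng.binomial(2, 0.8))
            else:
                n_female = int(rng.random() < 0.6)
                n_white = int(rng.random() < 0.65)
            rows.append(
                {
                    "home_id": f"h{i:03d}",
                    "n_residents": n_res,
                    "mci_home": arm.endswith("_mci"),
                    "mean_age": round(float(np.clip(rng.normal(age_mu, age_sd), 62, 95)), 1),
                    "n_female": n_female,
                    "n_male": n_res - n_female,
                    "n_white": n_white,
                    "n_other_ethnicity": n_res - n_white,
                    "mean_education": round(float(np.clip(rng.normal(15, 2.5), 8, 22)), 1),
                    "n_rooms": int(np.clip(round(rng.normal(rooms_mu, 1.5)), 4 + two_p, 12)),
                    "site": sites[i % 3],
                    "move_dates": "",
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("home_id", drop=False)


def simulate_cohort(scenario: SimScenario) -> SimulatedCohort:
    """Simulate the full four-arm cohort defined by the scenario."""
    metadata = make_metadata(scenario)
    all_events, all_reports, truth = [], [], {}
    for j, (home_id, meta) in enumerate(metadata.iterrows()):
        seed = np.random.SeedSequence([scenario.seed, 104729 + j]).generate_state(1)[0] % (2**31)
        ev, rep, gt = simulate_home(scenario, home_id, meta, int(seed))
        all_events.append(ev)
        all_reports.append(rep)
        truth[home_id] = gt
    events = pd.concat(all_events, ignore_index=True).sort_values(
        ["home_id", "sensor_id", "timestamp"], kind="stable"
    ).reset_index(drop=True)
    reports = pd.concat(all_reports, ignore_index=True)
    return SimulatedCohort(scenario, events, metadata, reports, truth)
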