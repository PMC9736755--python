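"""Synthetic participant-day generator for end-to-end testing of the pipeline.

Each simulated day is a tiling of behavior bouts — home rest, indoor
activity, outdoor walks (~4.5 km/h, ~100 steps/min), near-home strolls and
vehicle trips — from which 1-min accelerometer epochs and per-minute GPS
fixes are emitted with behavior-specific acceleration, step, availability,
accuracy and position-noise distributions. A ground-truth table maps every
minute to its bout kind, so trigger sensitivity and route recovery can be
scored against known walking episodes. Response behavior (answering
prompts, self-reporting walking) is an independent stochastic process with
kind-specific answer rates.

The generator makes no claim to realistic urban form: walking paths are
random-turn out-and-back polylines on the sphere, vehicle trips straight
lines, and positions jump back to home between excursions' endpoints only
through the bouts' own geometry (every excursion starts and ends at home).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as date_t
from datetime import datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geo import destination, geodesic_m
from .types import AccelEpoch, GpsFix, ParticipantDay, PromptEvent, PromptKind

BOUT_KINDS = ("home_rest", "indoor_active", "walk_outdoor", "stroll_near_home", "vehicle")


@dataclass(frozen=True)
class BehaviorBout:
    kind: str
    start: datetime
    end: datetime
    path: Optional[tuple[tuple[float, float], ...]] = None  # minute-resolution polyline

    @property
    def is_walking(self) -> bool:
        """Ground truth for 'walking outdoors' (near-home strolling is not)."""
        return self.kind == "walk_outdoor"

    @property
    def minutes(self) -> int:
        return int((self.end - self.start).total_seconds() // 60)


@dataclass(frozen=True)
class KindEmission:
    """Per-minute emission law of one behavior kind."""

    accel_mean: float  # g; per-epoch draws are N(mean, sd) truncated at 0
    accel_sd: float
    steps_mean: float  # steps/min
    steps_sd: float
    speed_kmh: float
    gps_available: float  # per-minute fix emission probability
    gps_accuracy_mean: float  # m
    gps_accuracy_sd: float
    gps_noise_sd: float  # m, isotropic position noise


def _default_emissions() -> dict[str, KindEmission]:
    return {
        "walk_outdoor": KindEmission(0.25, 0.05, 100, 15, 4.5, 0.95, 10, 5, 10),
        "home_rest": KindEmission(0.02, 0.01, 0, 0, 0.0, 0.10, 25, 15, 15),
        "vehicle": KindEmission(0.05, 0.02, 0, 0, 30.0, 0.90, 15, 8, 15),
        "indoor_active": KindEmission(0.15, 0.05, 30, 10, 0.0, 0.10, 25, 15, 15),
        "stroll_near_home": KindEmission(0.15, 0.05, 60, 15, 2.0, 0.90, 10, 5, 15),
    }


@dataclass(frozen=True)
class EmissionProfile:
    kinds: dict[str, KindEmission] = field(default_factory=_default_emissions)

    def clean(self) -> "EmissionProfile":
        """Noise-free identifiable limit: outdoor-walking GPS always available
        and exact; GPS silent for every other behavior (indoor unavailability
        is kept, otherwise a day of uninterrupted fixes would chain into one
        track segment and per-bout routes would not exist)."""
        kinds = {}
        for name, k in self.kinds.items():
            if name == "walk_outdoor":
                kinds[name] = replace(k, gps_available=1.0, gps_noise_sd=0.0)
            else:
                kinds[name] = replace(k, gps_available=0.0)
        return EmissionProfile(kinds)

    def with_walk_availability(self, p: float) -> "EmissionProfile":
        kinds = dict(self.kinds)
        kinds["walk_outdoor"] = replace(kinds["walk_outdoor"], gps_available=p)
        return EmissionProfile(kinds)


@dataclass(frozen=True)
class ScheduleProfile:
    """Bout counts and duration ranges (minutes) for one simulated day."""

    n_walk_bouts: int = 2
    walk_minutes: tuple[int, int] = (10, 40)
    n_indoor_bouts: int = 2
    indoor_minutes: tuple[int, int] = (20, 60)
    n_vehicle_bouts: int = 1
    vehicle_minutes: tuple[int, int] = (10, 30)
    n_stroll_bouts: int = 1
    stroll_minutes: tuple[int, int] = (5, 15)
    active_window: tuple[time, time] = (time(8, 0), time(20, 0))
    buffer_minutes: int = 5  # min separation between placed bouts
    wear_window: tuple[time, time] = (time(6, 0), time(22, 0))


@dataclass(frozen=True)
class ResponseProfile:
    """Answer rates per prompt kind and self-report fidelity."""

    p_answer_main: float = 0.655
    p_answer_repeated: float = 0.729
    p_answer_random: float = 0.756
    report_accuracy: float = 0.9  # P(report matches ground truth), both directions

    def p_answer(self, kind: PromptKind) -> float:
        return {
            PromptKind.main: self.p_answer_main,
            PromptKind.repeated: self.p_answer_repeated,
            PromptKind.random: self.p_answer_random,
        }[kind]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_schedule(
    day: date_t, profile: ScheduleProfile = ScheduleProfile(), seed: int | np.random.Generator = 0
) -> list[BehaviorBout]:
    """Draw a full-day bout tiling; deterministic given the seed.

    Excursion bouts (walks, vehicle trips, strolls, indoor activity) are
    placed without overlap inside the active window by rejection; home rest
    fills every remaining minute so the bouts tile 00:00-24:00 exactly.
    """
    rng = _rng(seed)
    day_start = datetime.combine(day, time(0, 0))
    w0 = day_start + timedelta(minutes=profile.active_window[0].hour * 60 + profile.active_window[0].minute)
    w1 = day_start + timedelta(minutes=profile.active_window[1].hour * 60 + profile.active_window[1].minute)
    window_min = int((w1 - w0).total_seconds() // 60)

    wanted = (
        [("walk_outdoor", profile.walk_minutes)] * profile.n_walk_bouts
        + [("indoor_active", profile.indoor_minutes)] * profile.n_indoor_bouts
        + [("vehicle", profile.vehicle_minutes)] * profile.n_vehicle_bouts
        + [("stroll_near_home", profile.stroll_minutes)] * profile.n_stroll_bouts
    )
    placed: list[tuple[int, int, str]] = []  # (start_min, end_min, kind) in window minutes
    for kind, (dlo, dhi) in wanted:
        dur = int(rng.integers(dlo, dhi + 1))
        if dur + 2 * profile.buffer_minutes > window_min:
            raise ValueError(f"{kind} bout of {dur} min cannot fit the active window")
        for _ in range(10_000):
            s = int(rng.integers(0, window_min - dur + 1))
            e = s + dur
            if all(
                e + profile.buffer_minutes <= ps or s >= pe + profile.buffer_minutes
                for ps, pe, _ in placed
            ):
                placed.append((s, e, kind))
                break
        else:
            raise ValueError("could not place all bouts; schedule profile too dense")

    placed.sort()
    bouts: list[BehaviorBout] = []
    cursor = day_start
    for s, e, kind in placed:
        bs, be = w0 + timedelta(minutes=s), w0 + timedelta(minutes=e)
        if bs > cursor:
            bouts.append(BehaviorBout("home_rest", cursor, bs))
        bouts.append(BehaviorBout(kind, bs, be))
        cursor = be
    day_end = day_start + timedelta(days=1)
    if cursor < day_end:
        bouts.append(BehaviorBout("home_rest", cursor, day_end))
    return bouts


def _bout_path(
    bout: BehaviorBout,
    home: tuple[float, float],
    emission: KindEmission,
    home_radius: float,
    rng: np.random.Generator,
) -> tuple[tuple[float, float], ...]:
    """Minute-resolution polyline for a bout (len = minutes + 1), home-anchored."""
    n = bout.minutes
    step_m = emission.speed_kmh * 1000.0 / 60.0
    if bout.kind in ("home_rest", "indoor_active") or step_m == 0:
        return tuple([home] * (n + 1))
    if bout.kind == "stroll_near_home":
        pts = [home]
        heading = float(rng.uniform(0, 360))
        for _ in range(n):
            heading += float(rng.normal(0, 60))
            cand = destination(pts[-1][0], pts[-1][1], heading, step_m)
            if geodesic_m(cand, home) > 0.8 * home_radius:
                # bounce back toward home to stay inside the geofence
                back = _bearing(pts[-1], home)
                cand = destination(pts[-1][0], pts[-1][1], back, step_m)
                heading = back
            pts.append(cand)
        return tuple(pts)
    # walk_outdoor and vehicle: out-and-back excursion starting/ending at home
    out_steps = (n + 1) // 2
    heading = float(rng.uniform(0, 360))
    turn_sd = 20.0 if bout.kind == "walk_outdoor" else 5.0
    outbound = [home]
    for _ in range(out_steps):
        heading += float(rng.normal(0, turn_sd))
        outbound.append(destination(outbound[-1][0], outbound[-1][1], heading, step_m))
    inbound = outbound[-2::-1][: n - out_steps]
    return tuple(outbound + inbound)


def _bearing(a: tuple[float, float], b: tuple[float, float]) -> float:
    import math

    lat1, lat2 = math.radians(a[0]), math.radians(b[0])
    dlon = math.radians(b[1] - a[1])
    x = math.sin(dlon) * math.cos(lat2)
    y = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    return math.degrees(math.atan2(x, y))


def emit_streams(
    schedule: Sequence[BehaviorBout],
    emission: EmissionProfile = EmissionProfile(),
    home: tuple[float, float] = (48.7758, 9.1829),
    seed: int | np.random.Generator = 0,
    wear_window: tuple[time, time] = (time(6, 0), time(22, 0)),
    home_radius: float = 100.0,
) -> tuple[list[AccelEpoch], list[GpsFix], pd.DataFrame, list[BehaviorBout]]:
    """Emit one epoch per minute 00:00-24:00 and per-minute GPS fixes.

    Returns (epochs, fixes, truth table, schedule with paths attached).
    Positions are true path vertices plus isotropic Gaussian noise of the
    behavior's stated sd; fix availability is an independent per-minute
    Bernoulli draw. The truth table maps each minute to its bout kind and
    walking flag.
    """
    rng = _rng(seed)
    epochs: list[AccelEpoch] = []
    fixes: list[GpsFix] = []
    truth_rows = []
    pathed: list[BehaviorBout] = []
    for bout in schedule:
        km = emission.kinds[bout.kind]
        path = _bout_path(bout, home, km, home_radius, rng)
        pathed.append(replace(bout, path=path))
        for m in range(bout.minutes):
            t = bout.start + timedelta(minutes=m)
            worn = wear_window[0] <= t.time() < wear_window[1]
            if worn:
                accel = float(np.clip(rng.normal(km.accel_mean, km.accel_sd), 0.0, 16.0))
                steps = int(max(0, round(rng.normal(km.steps_mean, km.steps_sd)))) if km.steps_mean > 0 else 0
            else:
                accel, steps = 0.0, 0
            epochs.append(AccelEpoch(t, accel, steps, worn))
            if rng.random() < km.gps_available:
                lat, lon = path[m]
                if km.gps_noise_sd > 0:
                    dn, de = rng.normal(0.0, km.gps_noise_sd, size=2)
                    lat, lon = destination(*destination(lat, lon, 0.0, dn), 90.0, de)
                accuracy = float(max(1.0, rng.normal(km.gps_accuracy_mean, km.gps_accuracy_sd)))
                fixes.append(GpsFix(t, lat, lon, accuracy))
            truth_rows.append({"minute": t, "kind": bout.kind, "is_walking": bout.is_walking})
    truth = pd.DataFrame(truth_rows, columns=["minute", "kind", "is_walking"])
    return epochs, fixes, truth, pathed


@dataclass
class SimulatedCohort:
    days: list[ParticipantDay]
    truth: dict[tuple[str, date_t], pd.DataFrame]
    schedules: dict[tuple[str, date_t], list[BehaviorBout]]
    homes: dict[str, tuple[float, float]]


def simulate_cohort(
    n_participants: int,
    n_days: int,
    seed: int,
    schedule_profile: ScheduleProfile = ScheduleProfile(),
    emission_profile: EmissionProfile = EmissionProfile(),
    start_date: date_t = date_t(2020, 9, 1),
    bbox: tuple[float, float, float, float] = (48.70, 9.10, 48.85, 9.25),
) -> SimulatedCohort:
    """Simulate a cohort of participant-days with per-participant home points
    sampled inside an urban bounding box; fully reproducible given the seed."""
    ss = np.random.SeedSequence(seed)
    cohort = SimulatedCohort([], {}, {}, {})
    part_seeds = ss.spawn(n_participants)
    for p in range(n_participants):
        pid = f"P{p + 1:03d}"
        prng = np.random.default_rng(part_seeds[p])
        home = (
            float(prng.uniform(bbox[0], bbox[2])),
            float(prng.uniform(bbox[1], bbox[3])),
        )
        cohort.homes[pid] = home
        for d in range(n_days):
            day = start_date + timedelta(days=d)
            schedule = sample_schedule(day, schedule_profile, prng)
            epochs, fixes, truth, pathed = emit_streams(
                schedule, emission_profile, home, prng, schedule_profile.wear_window
            )
            cohort.days.append(ParticipantDay(pid, day, epochs, fixes))
            cohort.truth[(pid, day)] = truth
            cohort.schedules[(pid, day)] = pathed
    return cohort


def walking_at(truth: pd.DataFrame, t: datetime) -> bool:
    """Ground-truth walking state of the minute containing ``t``."""
    minute = t.replace(second=0, microsecond=0)
    if t.second == 0 and t.microsecond == 0:
        minute = minute - timedelta(minutes=1)  # a tick at :00 reflects the minute just ended
    row = truth[truth["minute"] == minute]
    return bool(row["is_walking"].iloc[0]) if len(row) else False


def simulate_responses(
    prompts: Sequence[PromptEvent],
    truth: pd.DataFrame,
    response: ResponseProfile = ResponseProfile(),
    seed: int | np.random.Generator = 0,
) -> list[PromptEvent]:
    """Fill answered flags and self-reports on a prompt list.

    Answering is Bernoulli with the kind's rate; answered main/repeated
    prompts self-report the ground-truth walking state of their minute,
    flipped with probability 1 - report_accuracy.
    """
    rng = _rng(seed)
    out = []
    for p in prompts:
        answered = bool(rng.random() < response.p_answer(p.kind))
        report = None
        if answered and p.kind in (PromptKind.main, PromptKind.repeated):
            true_state = walking_at(truth, p.timestamp)
            report = true_state if rng.random() < response.report_accuracy else not true_state
        out.append(replace(p, answered=answered, self_report_walking=report))
    return out
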