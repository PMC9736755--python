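"""Deterministic event-log fixtures with prescribed count structure.

:func:`make_count_fixture` lays out, on a synthetic timeline, exactly the
requested numbers of walking routes, matched routes, prompts per kind,
answered prompts, self-report labels and GPS-present windows, so that the
evaluation pipeline reproduces any given set of ratios. This is the bridge
between published aggregate counts (the only deposited form of field data
of this kind) and the evaluation code: feed the counts in, run the real
pipeline, and the reported percentages must follow.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

from .geo import destination
from .routes import TrackSegment, WalkingRoute, route_metrics
from .types import AccelEpoch, GpsFix, PromptEvent, PromptKind


@dataclass(frozen=True)
class CountFixtureSpec:
    """Requested count structure. Defaults are all zero; set what you need.

    If ``n_main`` is smaller than ``n_trigger_matched`` (e.g. a pure
    sensitivity fixture), enough main prompts are created implicitly to
    realize the matching.
    """

    n_routes: int = 0
    n_trigger_matched: int = 0  # routes carrying >= 1 main/repeated prompt in-window
    n_random_matched: int = 0  # routes carrying >= 1 random prompt in-window
    n_main: int = 0
    n_main_answered: int = 0
    n_repeated: int = 0
    n_repeated_answered: int = 0
    n_random: int = 0
    n_random_answered: int = 0
    n_self_walking: int = 0  # of the answered mains
    gps_present_walking: int = 0  # mains with a fix in the 2-min window, per stratum
    gps_present_not_walking: int = 0
    gps_present_unanswered: int = 0

    def __post_init__(self) -> None:
        def req(cond: bool, msg: str) -> None:
            if not cond:
                raise ValueError(msg)

        for f in self.__dataclass_fields__:
            req(getattr(self, f) >= 0, f"{f} must be non-negative")
        req(self.n_trigger_matched <= self.n_routes, "matched routes exceed total routes")
        req(self.n_random_matched <= self.n_routes, "random-matched routes exceed total routes")
        req(self.n_main_answered <= self.n_main, "answered mains exceed mains")
        req(self.n_repeated_answered <= self.n_repeated, "answered repeats exceed repeats")
        req(self.n_random_answered <= self.n_random, "answered randoms exceed randoms")
        req(self.n_self_walking <= self.n_main_answered, "self-walking exceeds answered mains")

    @property
    def tracks_gps(self) -> bool:
        return (
            self.gps_present_walking
            + self.gps_present_not_walking
            + self.gps_present_unanswered
        ) > 0


@dataclass
class CountFixture:
    routes: list[WalkingRoute] = field(default_factory=list)
    prompts: list[PromptEvent] = field(default_factory=list)
    epochs: list[AccelEpoch] = field(default_factory=list)
    fixes: list[GpsFix] = field(default_factory=list)
    random_times: list[datetime] = field(default_factory=list)


# fixed per-stratum epoch emissions (two pre-prompt epochs each): steps/epoch, accel g
_STRATUM_EPOCHS = {
    "walking": (53, 0.25),
    "not_walking": (16, 0.12),
    "unanswered": (52, 0.22),
}

_SLOT_MIN = 30  # minutes per timeline slot; route + window + prompts fit well inside
_SLOTS_PER_DAY = 24  # packed 08:00-20:00 so everything stays in daytime hours


def make_count_fixture(
    spec: CountFixtureSpec,
    participant_id: str = "P001",
    base_date: datetime = datetime(2020, 9, 1),
    origin: tuple[float, float] = (48.7758, 9.1829),
    seed: int = 0,
) -> CountFixture:
    """Build streams realizing the requested counts exactly.

    Layout: a grid of 30-min slots, 24 per day starting 08:00. The first
    ``n_routes`` slots hold one short walking route each (two fixes 100 m /
    60 s apart, so every route rule holds); trigger-matched routes get
    their main prompt at the route end, random-matched routes a random
    prompt inside the route. All other prompts occupy later slots, far from
    any route window, so matched counts are exact. A main prompt sitting on
    a route is unavoidably GPS-present (the route's own fixes fall in its
    2-minute window), so matched mains are assigned to strata that still
    have GPS-present budget; a spec whose GPS budgets cannot absorb the
    matched mains is rejected. Layout is a pure function of the counts;
    ``seed`` is accepted for interface symmetry with the other generators.
    """
    fx = CountFixture()

    def slot_start(i: int) -> datetime:
        day, k = divmod(i, _SLOTS_PER_DAY)
        return base_date + timedelta(days=day, hours=8, minutes=_SLOT_MIN * k)

    # ---- routes (slots 0 .. n_routes-1)
    for i in range(spec.n_routes):
        t0 = slot_start(i)
        lat0, lon0 = destination(origin[0], origin[1], 90.0, 5.0 * i)
        lat1, lon1 = destination(lat0, lon0, 0.0, 100.0)
        seg = TrackSegment(
            (
                GpsFix(t0, lat0, lon0, 5.0),
                GpsFix(t0 + timedelta(seconds=60), lat1, lon1, 5.0),
            )
        )
        length, duration, speed = route_metrics(seg)
        fx.routes.append(WalkingRoute(seg, length, duration, speed))
        fx.fixes.extend(seg.fixes)
        if i < spec.n_random_matched:
            fx.random_times.append(t0 + timedelta(seconds=30))

    # ---- stratum bookkeeping for main prompts
    n_main_eff = max(spec.n_main, spec.n_trigger_matched)
    counts = {
        "walking": spec.n_self_walking,
        "not_walking": spec.n_main_answered - spec.n_self_walking,
        "unanswered": n_main_eff - spec.n_main_answered,
    }
    gps = {
        "walking": spec.gps_present_walking,
        "not_walking": spec.gps_present_not_walking,
        "unanswered": spec.gps_present_unanswered,
    }
    for name in counts:
        if gps[name] > counts[name]:
            raise ValueError(f"gps_present_{name} exceeds the {name} stratum size")

    mains: list[tuple[datetime, str, bool]] = []  # (time, stratum, add_gps_fix)
    # matched mains first: consume a GPS-present slot of some stratum
    for i in range(spec.n_trigger_matched):
        t = fx.routes[i].end  # inside [start, end + grace]: matched by construction
        for name in ("walking", "not_walking", "unanswered"):
            room = counts[name] > 0 and (not spec.tracks_gps or gps[name] > 0)
            if room:
                counts[name] -= 1
                if spec.tracks_gps:
                    gps[name] -= 1
                mains.append((t, name, False))
                break
        else:
            raise ValueError(
                "GPS-present stratum budgets cannot absorb the trigger-matched mains"
            )
    # remaining mains in prompt-only slots; first gps[name] of each get a window fix
    next_slot = spec.n_routes
    for name in ("walking", "not_walking", "unanswered"):
        for j in range(counts[name]):
            t = slot_start(next_slot) + timedelta(seconds=300)
            next_slot += 1
            mains.append((t, name, j < gps[name]))

    for t, stratum, add_fix in sorted(mains):
        answered = stratum != "unanswered"
        fx.prompts.append(
            PromptEvent(
                participant_id,
                t,
                PromptKind.main,
                answered=answered,
                self_report_walking=(stratum == "walking") if answered else None,
            )
        )
        steps, accel = _STRATUM_EPOCHS[stratum]
        fx.epochs.append(AccelEpoch(t - timedelta(seconds=120), accel, steps))
        fx.epochs.append(AccelEpoch(t - timedelta(seconds=60), accel, steps))
        if add_fix:
            fx.fixes.append(GpsFix(t - timedelta(seconds=30), origin[0], origin[1], 8.0))

    # ---- repeated prompts
    for j in range(spec.n_repeated):
        t = slot_start(next_slot) + timedelta(seconds=300)
        next_slot += 1
        fx.prompts.append(
            PromptEvent(
                participant_id,
                t,
                PromptKind.repeated,
                answered=j < spec.n_repeated_answered,
                self_report_walking=True if j < spec.n_repeated_answered else None,
            )
        )

    # ---- random prompts beyond the route-matched ones
    for j in range(spec.n_random - spec.n_random_matched):
        t = slot_start(next_slot) + timedelta(seconds=600)
        next_slot += 1
        fx.random_times.append(t)
    fx.random_times.sort()
    for j, t in enumerate(fx.random_times):
        fx.prompts.append(
            PromptEvent(participant_id, t, PromptKind.random, answered=j < spec.n_random_answered)
        )

    fx.prompts.sort(key=lambda p: p.timestamp)
    fx.epochs.sort(key=lambda e: e.timestamp)
    fx.fixes.sort(key=lambda f: f.timestamp)
    return fx
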