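"""The walking-trigger state machine.

The trigger distinguishes two states, stationary and nonstationary, ticking
once per minute over fused accelerometer epochs and GPS fixes. It switches
to nonstationary — and fires a *main* e-diary prompt — when, inside the
06:00-22:00 day window, movement acceleration has exceeded the threshold
(default 0.1 g) for a full sustain window (default 60 s) and the current
fix is both more than 100 m from the stationary anchor and outside the
100 m home geofence. While nonstationary, *repeated* prompts fire every
420 +/- 300 s (uniform jitter) for as long as the same conditions hold at
the scheduled fire time; a failed re-check reverts the state to stationary
and re-anchors at the current position. A separate time-based schedule
draws three *random* prompts per day in 10:00-22:00 at least 2.5 h apart.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from datetime import date as date_t
from datetime import datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np

from .config import TriggerConfig
from .geo import geodesic_m
from .types import AccelEpoch, GpsFix, PromptEvent, PromptKind


@dataclass(frozen=True)
class TriggerState:
    """Trigger memory between ticks.

    ``anchor`` is the last stationary location (set at the first valid fix,
    reset on every nonstationary->stationary reversion); ``next_repeat_at``
    is the scheduled follow-up fire time, set iff nonstationary.
    """

    mode: str = "stationary"  # "stationary" | "nonstationary"
    anchor: Optional[GpsFix] = None
    next_repeat_at: Optional[datetime] = None
    last_tick: Optional[datetime] = None


@dataclass(frozen=True)
class TriggerDecision:
    """Outcome of one tick; ``fired`` implies all three condition flags."""

    timestamp: datetime
    accel_ok: bool
    gps_ok: bool
    in_window: bool
    fired: Optional[PromptKind] = None


def accel_condition(epochs: Sequence[AccelEpoch], now: datetime, cfg: TriggerConfig) -> bool:
    """True iff every complete 1-min epoch in the trailing ``sustain`` seconds
    is worn and above the acceleration threshold (strict).

    Missing epochs in the window make the condition false (conservative).
    """
    need = int(cfg.sustain // 60)
    window_start = now - timedelta(seconds=cfg.sustain)
    covered = [
        e
        for e in epochs
        if e.timestamp >= window_start and e.timestamp + timedelta(seconds=60) <= now
    ]
    if len(covered) < need:
        return False
    return all(e.worn and e.movement_acceleration > cfg.accel_threshold for e in covered)


def gps_condition(
    fix: Optional[GpsFix], state: TriggerState, now: datetime, cfg: TriggerConfig
) -> bool:
    """True iff a fresh fix exists (age <= gps_staleness) that is more than
    ``move_radius`` from the anchor and outside the home geofence."""
    if fix is None or state.anchor is None:
        return False
    if (now - fix.timestamp).total_seconds() > cfg.gps_staleness:
        return False
    if geodesic_m(fix.point, state.anchor.point) <= cfg.move_radius:
        return False
    if geodesic_m(fix.point, cfg.home_point) <= cfg.home_radius:
        return False
    return True


def in_day_window(now: datetime, cfg: TriggerConfig) -> bool:
    return cfg.day_window[0] <= now.time() <= cfg.day_window[1]


def _draw_interval(rng: np.random.Generator, cfg: TriggerConfig) -> float:
    lo = cfg.repeat_interval - cfg.repeat_jitter
    hi = cfg.repeat_interval + cfg.repeat_jitter
    return float(rng.uniform(lo, hi))


def step(
    state: TriggerState,
    now: datetime,
    recent_epochs: Sequence[AccelEpoch],
    latest_fix: Optional[GpsFix],
    rng: np.random.Generator,
    cfg: TriggerConfig,
) -> tuple[TriggerState, TriggerDecision]:
    """Advance the state machine by one 60 s tick.

    Must be called in strictly increasing tick order (hard error otherwise).
    The jitter draw consumes the rng exactly once per fired prompt, at fire
    time, which keeps seeded runs reproducible.
    """
    if state.last_tick is not None and now <= state.last_tick:
        raise ValueError(f"tick {now} out of order (last was {state.last_tick})")

    # the anchor latches onto the first valid fix ever seen
    if state.anchor is None and latest_fix is not None:
        state = replace(state, anchor=latest_fix)

    accel_ok = accel_condition(recent_epochs, now, cfg)
    gps_ok = gps_condition(latest_fix, state, now, cfg)
    window = in_day_window(now, cfg)
    fired: Optional[PromptKind] = None

    if state.mode == "stationary":
        if accel_ok and gps_ok and window:
            fired = PromptKind.main
            state = replace(
                state,
                mode="nonstationary",
                next_repeat_at=now + timedelta(seconds=_draw_interval(rng, cfg)),
            )
    else:  # nonstationary: act only when the scheduled fire time has come
        if state.next_repeat_at is not None and now >= state.next_repeat_at:
            if accel_ok and gps_ok and window:
                fired = PromptKind.repeated
                state = replace(
                    state, next_repeat_at=now + timedelta(seconds=_draw_interval(rng, cfg))
                )
            else:
                state = replace(
                    state,
                    mode="stationary",
                    next_repeat_at=None,
                    anchor=latest_fix if latest_fix is not None else state.anchor,
                )

    state = replace(state, last_tick=now)
    return state, TriggerDecision(now, accel_ok, gps_ok, window, fired)


def run_trigger(
    participant_id: str,
    day: date_t,
    epochs: Sequence[AccelEpoch],
    fixes: Sequence[GpsFix],
    cfg: TriggerConfig,
    seed: int,
    return_decisions: bool = False,
):
    """Run the state machine over one participant-day at a 60 s tick.

    Ticks run from 00:01 local time to midnight of the next day, i.e. once
    after each epoch slot. Deterministic given the seed; returns the sorted
    prompt list (answered flags left False — response behavior is a separate
    process), and optionally the full per-tick decision trace.
    """
    rng = np.random.default_rng(seed)
    state = TriggerState()
    prompts: list[PromptEvent] = []
    decisions: list[TriggerDecision] = []

    epochs = sorted(epochs, key=lambda e: e.timestamp)
    fixes = sorted(fixes, key=lambda f: f.timestamp)
    fix_times = [f.timestamp for f in fixes]
    epoch_times = [e.timestamp for e in epochs]

    day_start = datetime.combine(day, time(0, 0))
    n_back = max(1, int(cfg.sustain // 60))
    for minute in range(1, 1441):
        now = day_start + timedelta(minutes=minute)
        # latest fix at or before the tick
        i = bisect.bisect_right(fix_times, now)
        latest = fixes[i - 1] if i > 0 else None
        # epochs overlapping the trailing sustain window
        j = bisect.bisect_right(epoch_times, now)
        recent = epochs[max(0, j - n_back - 1) : j]
        state, decision = step(state, now, recent, latest, rng, cfg)
        if return_decisions:
            decisions.append(decision)
        if decision.fired is not None:
            prompts.append(
                PromptEvent(participant_id=participant_id, timestamp=now, kind=decision.fired)
            )
    if return_decisions:
        return prompts, decisions
    return prompts


def schedule_random_prompts(
    day: date_t, cfg: TriggerConfig, seed: int | np.random.Generator
) -> list[datetime]:
    """Draw the day's time-based prompt schedule.

    Exactly ``random_count`` times uniform over the feasible set: all inside
    the random window with pairwise gaps >= ``random_min_gap`` (rejection
    sampling on the order statistics). Feasibility is enforced at config
    validation time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cfg.random_count == 0:
        return []
    w0, w1 = cfg.random_window
    day_start = datetime.combine(day, time(0, 0))
    lo = (w0.hour * 60 + w0.minute) * 60 + w0.second
    hi = (w1.hour * 60 + w1.minute) * 60 + w1.second
    while True:
        secs = sorted(int(round(s)) for s in rng.uniform(lo, hi, size=cfg.random_count))
        if all(b - a >= cfg.random_min_gap for a, b in zip(secs, secs[1:])):
            return [day_start + timedelta(seconds=s) for s in secs]
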