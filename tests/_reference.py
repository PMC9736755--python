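"""Independent brute-force reference implementations used as test oracles.

These re-derive the trigger and matching rules in the most literal way
possible — per-tick linear scans over the raw streams, no incremental
state beyond what the rules themselves mandate — so they can serve as
oracles for the optimized implementations without sharing code with them.
"""
from __future__ import annotations

from datetime import datetime, time, timedelta

import numpy as np

from walktrigger.geo import geodesic_m


def reference_trigger(participant_id, day, epochs, fixes, cfg, seed):
    """Straight-line interpreter of the walking-trigger rules.

    Returns [(timestamp, kind)] for one participant-day, ticking every
    minute and rescanning the full streams at each tick.
    """
    rng = np.random.default_rng(seed)
    events = []
    mode = "stationary"
    anchor = None
    next_repeat = None
    day_start = datetime.combine(day, time(0, 0))
    n_epochs_needed = cfg.sustain // 60

    for minute in range(1, 1441):
        now = day_start + timedelta(minutes=minute)

        latest = None
        for f in fixes:  # linear scan: latest fix at or before now
            if f.timestamp <= now:
                latest = f
        if anchor is None and latest is not None:
            anchor = latest

        window_start = now - timedelta(seconds=cfg.sustain)
        in_win_epochs = [
            e
            for e in epochs
            if e.timestamp >= window_start and e.timestamp + timedelta(seconds=60) <= now
        ]
        accel_ok = len(in_win_epochs) >= n_epochs_needed and all(
            e.worn and e.movement_acceleration > cfg.accel_threshold for e in in_win_epochs
        )

        gps_ok = (
            latest is not None
            and anchor is not None
            and (now - latest.timestamp).total_seconds() <= cfg.gps_staleness
            and geodesic_m((latest.lat, latest.lon), (anchor.lat, anchor.lon)) > cfg.move_radius
            and geodesic_m((latest.lat, latest.lon), cfg.home_point) > cfg.home_radius
        )

        in_window = cfg.day_window[0] <= now.time() <= cfg.day_window[1]

        if mode == "stationary":
            if accel_ok and gps_ok and in_window:
                events.append((now, "main"))
                mode = "nonstationary"
                u = rng.uniform(
                    cfg.repeat_interval - cfg.repeat_jitter,
                    cfg.repeat_interval + cfg.repeat_jitter,
                )
                next_repeat = now + timedelta(seconds=float(u))
        else:
            if next_repeat is not None and now >= next_repeat:
                if accel_ok and gps_ok and in_window:
                    events.append((now, "repeated"))
                    u = rng.uniform(
                        cfg.repeat_interval - cfg.repeat_jitter,
                        cfg.repeat_interval + cfg.repeat_jitter,
                    )
                    next_repeat = now + timedelta(seconds=float(u))
                else:
                    mode = "stationary"
                    next_repeat = None
                    if latest is not None:
                        anchor = latest
    return events


def reference_match(routes, prompt_times, grace_s=120.0):
    """Double loop over every route x prompt pair."""
    flags = []
    for r in routes:
        hit = False
        for t in prompt_times:
            if r.start <= t <= r.end + timedelta(seconds=grace_s):
                hit = True
        flags.append(hit)
    return flags
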