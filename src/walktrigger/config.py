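"""Validated configuration for the walking trigger and route reconstruction.

Every numeric constant of the method lives here with its published default:
the trigger fires when movement acceleration exceeds 0.1 g for at least one
minute while the phone's position is >100 m from its last stationary anchor
and outside a 100 m home geofence, within 06:00-22:00; follow-up prompts
repeat every 420 +/- 300 s while conditions persist; three additional random
prompts per day fall in 10:00-22:00 at least 2.5 h apart.
"""
from __future__ import annotations

from datetime import time
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class TriggerConfig(BaseModel):
    """Constants of the walking-trigger state machine. Units in field names' docs."""

    accel_threshold: float = Field(0.1, gt=0, description="movement-acceleration threshold, g")
    sustain: int = Field(60, gt=0, multiple_of=60, description="supra-threshold duration, s")
    move_radius: float = Field(100.0, gt=0, description="displacement radius from anchor, m")
    home_point: tuple[float, float] = Field(
        (48.7758, 9.1829), description="place of residence, (lat, lon) WGS84"
    )
    home_radius: float = Field(100.0, gt=0, description="home geofence radius, m")
    day_window: tuple[time, time] = Field(
        (time(6, 0), time(22, 0)), description="local-time window in which any prompt may fire"
    )
    repeat_interval: float = Field(420.0, gt=0, description="mean follow-up interval, s")
    repeat_jitter: float = Field(300.0, ge=0, description="symmetric jitter on the interval, s")
    random_count: int = Field(3, ge=0, description="random (time-based) prompts per day")
    random_window: tuple[time, time] = Field(
        (time(10, 0), time(22, 0)), description="local-time window for random prompts"
    )
    random_min_gap: float = Field(9000.0, gt=0, description="min spacing of random prompts, s")
    gps_staleness: float = Field(120.0, gt=0, description="max age of a usable GPS fix, s")

    @model_validator(mode="after")
    def _check(self) -> "TriggerConfig":
        if self.repeat_interval - self.repeat_jitter <= 0:
            raise ValueError(
                f"repeat_interval ({self.repeat_interval}) must exceed "
                f"repeat_jitter ({self.repeat_jitter})"
            )
        if self.day_window[0] >= self.day_window[1]:
            raise ValueError("day_window start must precede end")
        if self.random_window[0] >= self.random_window[1]:
            raise ValueError("random_window start must precede end")
        if self.random_count > 1:
            w0, w1 = self.random_window
            span = (w1.hour * 3600 + w1.minute * 60 + w1.second) - (
                w0.hour * 3600 + w0.minute * 60 + w0.second
            )
            need = (self.random_count - 1) * self.random_min_gap
            if span < need:
                raise ValueError(
                    f"random_window ({span} s) cannot fit {self.random_count} prompts "
                    f"spaced >= {self.random_min_gap} s (needs {need} s)"
                )
        return self


class RouteConfig(BaseModel):
    """The four walking-route filter rules plus the prompt-match grace period."""

    max_accuracy: float = Field(30.0, gt=0, description="max reported GPS error kept, m")
    min_gap: float = Field(60.0, gt=0, description="min spacing of retained fixes, s")
    max_gap: float = Field(120.0, gt=0, description="max spacing before a track splits, s")
    max_mean_speed: float = Field(10.0, gt=0, description="strict upper bound on route mean speed, km/h")
    min_length: float = Field(100.0, gt=0, description="min cumulative route length, m")
    match_grace: float = Field(120.0, ge=0, description="post-route window for prompt matching, s")

    @model_validator(mode="after")
    def _check(self) -> "RouteConfig":
        if not self.min_gap < self.max_gap:
            raise ValueError(f"min_gap ({self.min_gap}) must be < max_gap ({self.max_gap})")
        return self


def load_config(path: str | Path | None = None) -> tuple[TriggerConfig, RouteConfig]:
    """Load a YAML config with optional ``trigger:`` and ``route:`` sections.

    Unspecified keys take the method defaults; ``None`` returns pure defaults.
    Pydantic validation errors propagate (e.g. jitter >= repeat interval).
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    trig = TriggerConfig(**_coerce_windows(data.get("trigger", {}) or {}))
    route = RouteConfig(**(data.get("route", {}) or {}))
    return trig, route


def _coerce_windows(section: dict) -> dict:
    # allow "HH:MM" strings in YAML for the two time windows
    out = dict(section)
    for key in ("day_window", "random_window"):
        if key in out and out[key] is not None:
            out[key] = tuple(
                time.fromisoformat(v) if isinstance(v, str) else v for v in out[key]
            )
    if "home_point" in out and out["home_point"] is not None:
        out["home_point"] = tuple(out["home_point"])
    return out
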