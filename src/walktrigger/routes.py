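"""Walking-route reconstruction from raw GPS fixes.

A walking route is a contiguous GPS track that passes four filter rules:
(1) every fix has reported accuracy <= 30 m; (2) retained fixes are spaced
60-120 s apart (streams sampled faster are greedily thinned to >= 60 s,
and the track splits wherever a gap exceeds 120 s); (3) the mean speed of
the whole route is below 10 km/h; (4) the cumulative path length is at
least 100 m. Routes serve as reference data for trigger sensitivity: they
are computed from GPS alone, independently of any prompt.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

from .config import RouteConfig
from .geo import geodesic_m
from .types import GpsFix


@dataclass(frozen=True)
class TrackSegment:
    """A run of retained fixes whose consecutive gaps all lie in [min_gap, max_gap]."""

    fixes: tuple[GpsFix, ...]

    @property
    def start(self) -> datetime:
        return self.fixes[0].timestamp

    @property
    def end(self) -> datetime:
        return self.fixes[-1].timestamp


@dataclass(frozen=True)
class WalkingRoute:
    """A track segment passing the speed and length rules, with derived metrics."""

    segment: TrackSegment
    length: float  # cumulative haversine path length, m
    duration: float  # s
    mean_speed: float  # km/h

    @property
    def start(self) -> datetime:
        return self.segment.start

    @property
    def end(self) -> datetime:
        return self.segment.end


def filter_fixes(fixes: list[GpsFix], cfg: RouteConfig) -> list[GpsFix]:
    """Keep exactly the fixes with reported accuracy <= max_accuracy, order preserved."""
    return [f for f in fixes if f.accuracy <= cfg.max_accuracy]


def segment_tracks(fixes: list[GpsFix], cfg: RouteConfig) -> list[TrackSegment]:
    """Thin to >= min_gap spacing (greedy from the stream start), then split at
    gaps > max_gap; segments need at least two fixes to describe movement."""
    if not fixes:
        return []
    thinned = [fixes[0]]
    for f in fixes[1:]:
        if (f.timestamp - thinned[-1].timestamp).total_seconds() >= cfg.min_gap:
            thinned.append(f)
    segments: list[TrackSegment] = []
    current = [thinned[0]]
    for f in thinned[1:]:
        if (f.timestamp - current[-1].timestamp).total_seconds() > cfg.max_gap:
            if len(current) >= 2:
                segments.append(TrackSegment(tuple(current)))
            current = [f]
        else:
            current.append(f)
    if len(current) >= 2:
        segments.append(TrackSegment(tuple(current)))
    return segments


def route_metrics(segment: TrackSegment) -> tuple[float, float, float]:
    """(cumulative length m, duration s, mean speed km/h) of a segment."""
    pts = [f.point for f in segment.fixes]
    length = sum(geodesic_m(pts[i], pts[i + 1]) for i in range(len(pts) - 1))
    duration = (segment.end - segment.start).total_seconds()
    speed = (length / 1000.0) / (duration / 3600.0) if duration > 0 else float("inf")
    return length, duration, speed


def reconstruct_routes(fixes: list[GpsFix], cfg: RouteConfig | None = None) -> list[WalkingRoute]:
    """Full pipeline: accuracy filter -> spacing/segmentation -> speed & length rules."""
    cfg = cfg or RouteConfig()
    routes = []
    for seg in segment_tracks(filter_fixes(fixes, cfg), cfg):
        length, duration, speed = route_metrics(seg)
        if length >= cfg.min_length and speed < cfg.max_mean_speed and duration > 0:
            routes.append(WalkingRoute(seg, length, duration, speed))
    return routes
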