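"""Validation analyses for the walking trigger.

Two descriptive analyses mirror the method's evaluation protocol:

* **Sensitivity** — of all independently reconstructed walking routes, the
  fraction during which (or within a 2-min grace period after which) at
  least one triggered e-diary (main or repeated) fired; a time-based
  comparator applies the identical matching rule to the day's random
  prompts instead.
* **Specificity** — a contrast of objectively measured activity (steps,
  movement acceleration, GPS presence) in the 2 minutes before each main
  prompt, stratified by whether the participant self-reported walking
  outdoors, denied it, or left the prompt unanswered.

Plus compliance rates per prompt kind and the 8-hour wear-time validity rule.
All percentages are rounded half-up to one decimal.
"""
from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RouteConfig
from .routes import WalkingRoute
from .types import AccelEpoch, GpsFix, ParticipantDay, PromptEvent, PromptKind


def pct(numerator: float, denominator: float) -> Optional[float]:
    """Percentage rounded half-up to one decimal; None on empty denominator."""
    if denominator == 0:
        return None
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ------------------------------------------------------------- sensitivity

@dataclass
class SensitivityReport:
    n_routes: int
    n_matched: int
    sensitivity_pct: Optional[float]  # None (flagged undefined) when n_routes == 0
    comparator_matched: Optional[int] = None
    comparator_pct: Optional[float] = None


def match_routes(
    routes: Sequence[WalkingRoute],
    prompts: Sequence[PromptEvent],
    cfg: RouteConfig | None = None,
    kinds: tuple[PromptKind, ...] = (PromptKind.main, PromptKind.repeated),
) -> tuple[list[bool], SensitivityReport]:
    """Flag each route as matched iff >= 1 prompt of the given kinds falls in
    [route.start, route.end + match_grace], inclusive at both ends."""
    cfg = cfg or RouteConfig()
    times = sorted(p.timestamp for p in prompts if p.kind in kinds)
    grace = timedelta(seconds=cfg.match_grace)
    flags = []
    for r in routes:
        i = bisect.bisect_left(times, r.start)
        flags.append(i < len(times) and times[i] <= r.end + grace)
    n = len(routes)
    matched = sum(flags)
    return flags, SensitivityReport(n, matched, pct(matched, n))


def time_based_comparator(
    routes: Sequence[WalkingRoute],
    random_times: Sequence[datetime],
    cfg: RouteConfig | None = None,
) -> tuple[int, Optional[float]]:
    """Apply the route-matching rule to time-based (random) prompt times only."""
    cfg = cfg or RouteConfig()
    pseudo = [
        PromptEvent("", t, PromptKind.main) for t in random_times
    ]  # reuse the matcher; kind is irrelevant to the rule
    flags, rep = match_routes(routes, pseudo, cfg)
    return rep.n_matched, rep.sensitivity_pct


# ------------------------------------------------------------- specificity

@dataclass
class PrePromptActivity:
    steps: int
    n_epochs: int
    mean_acceleration: Optional[float]
    above_low: bool  # window acceleration > 0.1 g
    above_high: bool  # window acceleration >= 0.2 g
    gps_present: bool


def pre_prompt_activity(
    prompt: PromptEvent,
    epochs: Sequence[AccelEpoch],
    fixes: Sequence[GpsFix],
    window: float = 120.0,
    low_threshold: float = 0.1,
    high_threshold: float = 0.2,
    mode: str = "window_mean",
) -> PrePromptActivity:
    """Objective activity in the ``window`` seconds before a main prompt.

    Steps are summed over the complete 1-min epochs preceding the prompt.
    The acceleration flags compare the window-mean epoch acceleration
    (default) or, with ``mode='any_epoch'``, any single epoch, against the
    two thresholds: strictly above 0.1 g, at or above 0.2 g. GPS is present
    iff any fix falls in [t - window, t].
    """
    t = prompt.timestamp
    t0 = t - timedelta(seconds=window)
    win = [e for e in epochs if e.timestamp >= t0 and e.timestamp + timedelta(seconds=60) <= t]
    steps = sum(e.steps for e in win)
    accels = [e.movement_acceleration for e in win]
    if not accels:
        mean_a, above_low, above_high = None, False, False
    elif mode == "window_mean":
        mean_a = float(np.mean(accels))
        above_low, above_high = mean_a > low_threshold, mean_a >= high_threshold
    elif mode == "any_epoch":
        mean_a = float(np.mean(accels))
        above_low = any(a > low_threshold for a in accels)
        above_high = any(a >= high_threshold for a in accels)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    gps = any(t0 <= f.timestamp <= t for f in fixes)
    return PrePromptActivity(steps, len(win), mean_a, above_low, above_high, gps)


STRATA = ("walking", "not_walking", "unanswered")


def _stratum(p: PromptEvent) -> str:
    if not p.answered:
        return "unanswered"
    return "walking" if p.self_report_walking else "not_walking"


def pre_prompt_table(
    prompts: Sequence[PromptEvent],
    epochs: Sequence[AccelEpoch],
    fixes: Sequence[GpsFix],
    window: float = 120.0,
    mode: str = "window_mean",
) -> pd.DataFrame:
    """Per-main-prompt activity records with stratum labels (analysis table)."""
    epochs = sorted(epochs, key=lambda e: e.timestamp)
    fixes = sorted(fixes, key=lambda f: f.timestamp)
    etimes = [e.timestamp for e in epochs]
    ftimes = [f.timestamp for f in fixes]
    rows = []
    for p in prompts:
        if p.kind is not PromptKind.main:
            continue
        # narrow the streams before delegating; keeps the rule in one place
        lo = bisect.bisect_left(etimes, p.timestamp - timedelta(seconds=window + 60))
        hi = bisect.bisect_right(etimes, p.timestamp)
        flo = bisect.bisect_left(ftimes, p.timestamp - timedelta(seconds=window))
        fhi = bisect.bisect_right(ftimes, p.timestamp)
        act = pre_prompt_activity(p, epochs[lo:hi], fixes[flo:fhi], window=window, mode=mode)
        rows.append(
            {
                "participant_id": p.participant_id,
                "timestamp": p.timestamp,
                "stratum": _stratum(p),
                "steps": act.steps,
                "n_epochs": act.n_epochs,
                "mean_acceleration": act.mean_acceleration,
                "above_0_1g": act.above_low,
                "at_or_above_0_2g": act.above_high,
                "gps_present": act.gps_present,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "timestamp",
            "stratum",
            "steps",
            "n_epochs",
            "mean_acceleration",
            "above_0_1g",
            "at_or_above_0_2g",
            "gps_present",
        ],
    )


@dataclass
class StratumStats:
    n: int
    share_pct: Optional[float]  # share among all main prompts
    mean_steps: Optional[float]
    sd_steps: Optional[float]
    pct_above_0_1g: Optional[float]
    pct_at_or_above_0_2g: Optional[float]
    pct_with_gps: Optional[float]


@dataclass
class SpecificityReport:
    n_main: int
    n_answered: int
    pct_self_walking: Optional[float]  # walking share among answered mains
    strata: dict[str, StratumStats] = field(default_factory=dict)


def specificity_report(
    prompts: Sequence[PromptEvent],
    epochs: Sequence[AccelEpoch],
    fixes: Sequence[GpsFix],
    window: float = 120.0,
    mode: str = "window_mean",
) -> SpecificityReport:
    """Stratified pre-prompt activity contrast over all main prompts."""
    table = pre_prompt_table(prompts, epochs, fixes, window=window, mode=mode)
    n_main = len(table)
    n_answered = int((table["stratum"] != "unanswered").sum()) if n_main else 0
    n_walk = int((table["stratum"] == "walking").sum()) if n_main else 0
    report = SpecificityReport(n_main, n_answered, pct(n_walk, n_answered))
    for name in STRATA:
        sub = table[table["stratum"] == name] if n_main else table
        n = len(sub)
        if n == 0:
            report.strata[name] = StratumStats(0, pct(0, n_main), None, None, None, None, None)
            continue
        sd = float(sub["steps"].std(ddof=1)) if n > 1 else 0.0
        report.strata[name] = StratumStats(
            n=n,
            share_pct=pct(n, n_main),
            mean_steps=float(sub["steps"].mean()),
            sd_steps=sd,
            pct_above_0_1g=pct(int(sub["above_0_1g"].sum()), n),
            pct_at_or_above_0_2g=pct(int(sub["at_or_above_0_2g"].sum()), n),
            pct_with_gps=pct(int(sub["gps_present"].sum()), n),
        )
    return report


def acceleration_histogram(
    table: pd.DataFrame, bin_width: float = 0.05, max_g: float = 1.0
) -> pd.DataFrame:
    """Per-stratum histogram of pre-prompt window-mean acceleration (CSV-ready)."""
    edges = np.arange(0.0, max_g + bin_width, bin_width)
    out = []
    for name, sub in table.dropna(subset=["mean_acceleration"]).groupby("stratum"):
        counts, _ = np.histogram(sub["mean_acceleration"], bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            out.append({"stratum": name, "bin_low_g": round(lo, 3), "bin_high_g": round(hi, 3), "count": int(c)})
    return pd.DataFrame(out, columns=["stratum", "bin_low_g", "bin_high_g", "count"])


# ------------------------------------------------------------- compliance

@dataclass
class KindCompliance:
    prompted: int
    answered: int
    rate_pct: Optional[float]


@dataclass
class ComplianceReport:
    by_kind: dict[str, KindCompliance]
    triggered: KindCompliance  # main + repeated (trigger-produced prompts)
    overall: KindCompliance  # all kinds


def compliance_report(prompts: Sequence[PromptEvent]) -> ComplianceReport:
    by_kind = {}
    for kind in PromptKind:
        of_kind = [p for p in prompts if p.kind is kind]
        answered = sum(p.answered for p in of_kind)
        by_kind[kind.value] = KindCompliance(len(of_kind), answered, pct(answered, len(of_kind)))
    trig_p = by_kind["main"].prompted + by_kind["repeated"].prompted
    trig_a = by_kind["main"].answered + by_kind["repeated"].answered
    all_p = trig_p + by_kind["random"].prompted
    all_a = trig_a + by_kind["random"].answered
    return ComplianceReport(
        by_kind=by_kind,
        triggered=KindCompliance(trig_p, trig_a, pct(trig_a, trig_p)),
        overall=KindCompliance(all_p, all_a, pct(all_a, all_p)),
    )


# ------------------------------------------------------------- validity

def day_validity(day: ParticipantDay, min_wear_hours: float = 8.0) -> bool:
    """A participant-day is analyzable iff accelerometer wear time >= 8 h."""
    return day.wear_hours >= min_wear_hours


def filter_valid_days(
    days: Sequence[ParticipantDay], min_wear_hours: float = 8.0
) -> tuple[list[ParticipantDay], int]:
    """(valid days, number excluded for insufficient wear time)."""
    valid = [d for d in days if day_validity(d, min_wear_hours)]
    return valid, len(days) - len(valid)


def report_to_dict(report) -> dict:
    """Recursively convert any report dataclass to JSON-serializable primitives."""
    if hasattr(report, "__dataclass_fields__"):
        return {k: report_to_dict(getattr(report, k)) for k in report.__dataclass_fields__}
    if isinstance(report, dict):
        return {k: report_to_dict(v) for k, v in report.items()}
    if isinstance(report, (list, tuple)):
        return [report_to_dict(v) for v in report]
    if isinstance(report, float) and math.isnan(report):
        return None
    if isinstance(report, (np.floating, np.integer)):
        return report.item()
    if isinstance(report, datetime):
        return report.isoformat()
    return report
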