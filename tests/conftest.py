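from datetime import date, datetime, timedelta

import pytest

from walktrigger import EmissionProfile, RouteConfig, ScheduleProfile, TriggerConfig
from walktrigger.geo import destination
from walktrigger.types import AccelEpoch, GpsFix

HOME = (48.7758, 9.1829)
DAY = date(2020, 9, 7)


@pytest.fixture
def trigger_cfg() -> TriggerConfig:
    return TriggerConfig(home_point=HOME)


@pytest.fixture
def derand_cfg() -> TriggerConfig:
    """Jitter-free config: the repeat schedule becomes a fixed 420 s grid."""
    return TriggerConfig(home_point=HOME, repeat_jitter=0)


@pytest.fixture
def route_cfg() -> RouteConfig:
    return RouteConfig()


def straight_walk(
    start: datetime,
    minutes: int,
    origin=HOME,
    speed_m_per_min: float = 75.0,
    bearing: float = 45.0,
    accel: float = 0.25,
    steps: int = 100,
    accuracy: float = 5.0,
):
    """A straight outbound walk: one epoch and one on-path fix per minute.

    Fix at minute m sits m * speed metres from the origin; epochs cover
    [start, start + minutes). Used to hand-derive trigger schedules.
    """
    epochs, fixes = [], []
    for m in range(minutes + 1):
        t = start + timedelta(minutes=m)
        if m < minutes:
            epochs.append(AccelEpoch(t, accel, steps))
        lat, lon = destination(origin[0], origin[1], bearing, speed_m_per_min * m)
        fixes.append(GpsFix(t, lat, lon, accuracy))
    return epochs, fixes


@pytest.fixture
def clean_emission() -> EmissionProfile:
    return EmissionProfile().clean()


@pytest.fixture
def schedule_profile() -> ScheduleProfile:
    return ScheduleProfile()
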