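"""Core domain records exchanged between the sensing, trigger and evaluation layers.

Timestamps throughout the package are naive local civil time of the study
site: the trigger's 06:00-22:00 day window and the 10:00-22:00 random-prompt
window are wall-clock rules, so local time is the natural frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as date_t
from datetime import datetime
from enum import Enum
from typing import Optional


class ValidationError(ValueError):
    """A stream or record violates a domain invariant."""


class FormatError(ValueError):
    """A file does not parse in the named format / misses required columns."""


class PromptKind(str, Enum):
    """E-diary prompt provenance.

    ``main``     — first prompt of a detected walking episode;
    ``repeated`` — follow-up while trigger conditions persist;
    ``random``   — time-based prompt from the daily random schedule.
    """

    main = "main"
    repeated = "repeated"
    random = "random"


@dataclass(frozen=True)
class AccelEpoch:
    """One minute of accelerometry: epoch start time, movement acceleration
    magnitude in g (gravity-removed), step count, and wear flag."""

    timestamp: datetime
    movement_acceleration: float
    steps: int
    worn: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.movement_acceleration <= 16.0):
            raise ValidationError(
                f"movement_acceleration {self.movement_acceleration} outside [0, 16] g"
            )
        if self.steps < 0:
            raise ValidationError(f"steps {self.steps} < 0")


@dataclass(frozen=True)
class GpsFix:
    """A timestamped WGS84 position with reported horizontal accuracy (m)."""

    timestamp: datetime
    lat: float
    lon: float
    accuracy: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValidationError(f"lat {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValidationError(f"lon {self.lon} outside [-180, 180]")
        if not self.accuracy > 0:
            raise ValidationError(f"accuracy {self.accuracy} must be > 0")

    @property
    def point(self) -> tuple[float, float]:
        return (self.lat, self.lon)


@dataclass(frozen=True)
class PromptEvent:
    """One e-diary prompt: who, when, which kind, whether answered, and —
    for answered main/repeated prompts — the self-reported walking state."""

    participant_id: str
    timestamp: datetime
    kind: PromptKind
    answered: bool = False
    self_report_walking: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.self_report_walking is not None:
            if not self.answered:
                raise ValidationError("unanswered prompt cannot carry a self-report")
            if self.kind is PromptKind.random:
                raise ValidationError("random prompts carry no walking self-report")


def validate_epoch_stream(epochs: list[AccelEpoch]) -> None:
    """Epochs must be strictly increasing on a 60 s grid (gaps allowed).

    Raises :class:`ValidationError` naming the first offending row.
    """
    for i in range(1, len(epochs)):
        delta = (epochs[i].timestamp - epochs[i - 1].timestamp).total_seconds()
        if delta <= 0:
            raise ValidationError(
                f"epoch timestamps not strictly increasing at row {i} "
                f"({epochs[i].timestamp} after {epochs[i - 1].timestamp})"
            )
        if delta % 60 != 0:
            raise ValidationError(
                f"epoch spacing {delta:.0f} s at row {i} is not a multiple of 60 s"
            )


def validate_fix_stream(fixes: list[GpsFix]) -> None:
    """Fix timestamps must be strictly increasing."""
    for i in range(1, len(fixes)):
        if fixes[i].timestamp <= fixes[i - 1].timestamp:
            raise ValidationError(
                f"fix timestamps not strictly increasing at row {i} "
                f"({fixes[i].timestamp})"
            )


@dataclass
class ParticipantDay:
    """All streams of one participant on one calendar day."""

    participant_id: str
    date: date_t
    epochs: list[AccelEpoch] = field(default_factory=list)
    fixes: list[GpsFix] = field(default_factory=list)
    prompts: list[PromptEvent] = field(default_factory=list)

    @property
    def wear_hours(self) -> float:
        """Hours of accelerometer wear, i.e. worn 1-min epochs / 60."""
        return sum(1 for e in self.epochs if e.worn) / 60.0
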