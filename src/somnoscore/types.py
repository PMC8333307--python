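"""Core in-memory containers for polysomnography (PSG) studies.

A :class:`Study` bundles everything one overnight recording carries: the
channel map (EEG/EOG/EMG/ECG, airflow, effort belts, SpO2, body position,
audio), the hypnogram (sleep stage per 30 s epoch), the scored event list and
the patient metadata.  Events follow the dataset's family/type taxonomy; time
coordinates are 0-based seconds from recording start, intervals are half-open
``[start, start + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

# Sleep stage labels (AASM): Wake, N1-N3 (non-REM), REM.
SLEEP_STAGES = ("W", "N1", "N2", "N3", "R")
DEFAULT_EPOCH_S = 30.0

#: Legal event types per family (the annotation sidecar taxonomy).
EVENT_TAXONOMY: dict[str, tuple[str, ...]] = {
    "Respiratory": (
        "ObstructiveApnea",
        "CentralApnea",
        "MixedApnea",
        "Hypopnea",
        "CheyneStokesRespiration",
        "PeriodicRespiration",
        "RERA",
    ),
    "Neurological": ("Arousal",),
    "Limb": (
        "LegMovement",
        "AlternatingLegMuscleActivation",
        "HypnagogicFootTremor",
        "ExcessiveFragmentaryMyoclonus",
        "RhythmicMovementDisorder",
    ),
    "Nasal": ("Snore",),
    "Cardiac": (
        "Bradycardia",
        "Tachycardia",
        "LongRR",
        "PttDrop",
        "HeartRateDrop",
        "HeartRateRise",
        "Asystole",
        "SinusTachycardia",
        "NarrowComplexTachycardia",
        "WideComplexTachycardia",
        "AtrialFibrillation",
    ),
    "SpO2": ("RelativeDesaturation", "AbsoluteDesaturation"),
}

#: The four apnea/hypopnea types that enter AHI and the screening stage.
APNEA_TYPES = ("ObstructiveApnea", "CentralApnea", "MixedApnea")
RESPIRATORY_SCORED_TYPES = APNEA_TYPES + ("Hypopnea",)

#: Minimum duration of an acceptable apneic episode (seconds).
MIN_EVENT_DURATION_S = 10.0


class TaxonomyError(ValueError):
    """Raised for an event type that is illegal under its family."""


@dataclass(frozen=True)
class EventAnnotation:
    """One scored event: family, type, onset and duration in seconds."""

    family: str
    type: str
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.family not in EVENT_TAXONOMY:
            raise TaxonomyError(f"unknown event family {self.family!r}")
        if self.type not in EVENT_TAXONOMY[self.family]:
            raise TaxonomyError(
                f"event type {self.type!r} is not legal for family {self.family!r}"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class Signal:
    """One channel's samples plus the EDF scaling metadata.

    ``physical_min/max`` and ``digital_min/max`` define the affine map used
    when the channel is written to a 16-bit EDF record.
    """

    label: str
    samples: np.ndarray
    fs: float
    physical_min: float = -100.0
    physical_max: float = 100.0
    digital_min: int = -32768
    digital_max: int = 32767

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def time_slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples in the half-open interval [start_s, end_s), clipped."""
        i0 = max(0, int(round(start_s * self.fs)))
        i1 = min(len(self.samples), int(round(end_s * self.fs)))
        return self.samples[i0:i1]


@dataclass
class Study:
    """A full recording: channels, hypnogram, events, patient metadata."""

    patient_id: int
    age: int
    gender: str
    channels: dict[str, Signal] = field(default_factory=dict)
    hypnogram: list[tuple[int, str]] = field(default_factory=list)
    events: list[EventAnnotation] = field(default_factory=list)
    epoch_s: float = DEFAULT_EPOCH_S
    recording_time_h: float = 0.0

    def __post_init__(self) -> None:
        if self.patient_id <= 0:
            raise ValueError("patient_id must be a positive integer")
        if self.gender not in ("M", "F"):
            raise ValueError("gender must be 'M' or 'F'")
        for _, stage in self.hypnogram:
            if stage not in SLEEP_STAGES:
                raise ValueError(f"unknown sleep stage {stage!r}")
        durs = {round(sig.duration_s, 3) for sig in self.channels.values()}
        if len(durs) > 1 and max(durs) - min(durs) > 1.0:
            raise ValueError(f"channel durations disagree: {sorted(durs)}")

    @property
    def duration_s(self) -> float:
        if self.channels:
            return max(sig.duration_s for sig in self.channels.values())
        return self.recording_time_h * 3600.0

    def events_of(self, *types: str) -> list[EventAnnotation]:
        return [e for e in self.events if e.type in types]

    @property
    def respiratory_events(self) -> list[EventAnnotation]:
        return self.events_of(*RESPIRATORY_SCORED_TYPES)


def sort_events(events: Iterable[EventAnnotation]) -> list[EventAnnotation]:
    return sorted(events, key=lambda e: (e.start_s, e.type))


__all__ = [
    "APNEA_TYPES",
    "DEFAULT_EPOCH_S",
    "EVENT_TAXONOMY",
    "EventAnnotation",
    "MIN_EVENT_DURATION_S",
    "RESPIRATORY_SCORED_TYPES",
    "SLEEP_STAGES",
    "Signal",
    "Study",
    "TaxonomyError",
    "replace",
    "sort_events",
]
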