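"""Synthetic polysomnography generator with known ground truth.

Emulates the signal content a sleep-apnea study needs downstream: quasi-
periodic breathing flow on the two nasal sensors (pressure cannula and
thermistor), amplitude-reduction events of the four apnea/hypopnea types,
SpO2 desaturations lagged after events, arousals, a hypnogram, and a
breathing-correlated audio surrogate on the tracheal/ambient microphone
channels — plus a two-device recording pair with a known start-time offset
for exercising the synchronization stage.

The breathing waveform is a train of raised-cosine inhale/exhale bursts (a
normal breath lasts roughly 3–5 s) rather than a pure sinusoid, so the flow
envelope has realistic short-time structure.  Events multiply the flow
envelope by ``1 − reduction`` per sensor; when ``residual_breathing`` is
false the in-event oscillation is replaced by a slow (0.07 Hz) wander of the
same reduced amplitude, so the planned reduction stays recoverable from the
envelope while the in-event dominant frequency falls below the normal
breathing band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .channels import CHANNEL_TABLE, FLOW_KEYS, spec_for
from .types import (
    EventAnnotation,
    MIN_EVENT_DURATION_S,
    RESPIRATORY_SCORED_TYPES,
    Signal,
    Study,
)

#: Per-type mean event durations (s) used to calibrate random plans;
#: documented constants from clinical scoring practice for this cohort style.
TYPE_MEAN_DURATION_S = {
    "MixedApnea": 24.6457,
    "ObstructiveApnea": 19.0656,
    "CentralApnea": 16.1016,
    "Hypopnea": 16.162,
}
MAX_EVENT_DURATION_S = 128.5

#: Frequency of the non-oscillatory in-event wander (Hz); below the normal
#: breathing band so a full cessation never triggers the breathing-rate rule.
_WANDER_HZ = 0.07

AUDIO_CHANNELS = ("Snore", "Tracheal", "Microphone")
AUX_CHANNELS = (
    "EEG A1-A2", "EEG C3-A2", "EEG C4-A1", "EOG LOC-A2", "EOG ROC-A2",
    "EMG Chin", "Leg 1", "Leg 2", "ECG I", "RR", "Effort THO", "Effort ABD",
    "Body", "PulseRate",
)


@dataclass(frozen=True)
class PlannedEvent:
    """Ground-truth respiratory event to inject into the flow channels."""

    type: str
    start_s: float
    duration_s: float
    reduction_cannula: float
    reduction_thermistor: float
    residual_breathing: bool = False
    with_desat: bool | None = None
    with_arousal: bool | None = None

    def __post_init__(self) -> None:
        if self.type not in RESPIRATORY_SCORED_TYPES:
            raise ValueError(f"unknown respiratory event type {self.type!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for r in (self.reduction_cannula, self.reduction_thermistor):
            if not 0.0 <= r <= 1.0:
                raise ValueError("reduction fractions must lie in [0, 1]")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class SimulationConfig:
    """All generative knobs of one synthetic study."""

    duration_h: float = 1.0
    seed: int = 0
    breathing_rate_hz: float = 0.25
    event_plan: list[PlannedEvent] = field(default_factory=list)
    desat_prob: float = 0.7
    desat_lag_s: float = 25.0
    arousal_prob: float = 0.8
    arousal_lag_s: float = 2.5
    device_offset_s: float = 0.0
    noise_level: float = 0.05
    hypnogram_plan: list[str] | None = None
    epoch_s: float = 30.0
    min_event_duration_s: float = MIN_EVENT_DURATION_S
    breathing_amplitude: float = 50.0     # a.u., inside the ±100 physical range
    desat_depth: float = 4.0              # % SpO2 drop for flagged events
    desat_duration_s: float = 20.0
    arousal_duration_s: float = 3.0
    spo2_baseline: float = 96.0
    spo2_floor: float = 70.0
    audio_channels: tuple[str, ...] = AUDIO_CHANNELS
    aux_channels: tuple[str, ...] = AUX_CHANNELS
    patient_id: int = 993
    age: int = 57
    gender: str = "M"

    def validate(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if not 0.16 <= self.breathing_rate_hz <= 0.4:
            raise ValueError("breathing_rate_hz must lie in [0.16, 0.4]")
        for p in (self.desat_prob, self.arousal_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        total_s = self.duration_h * 3600.0
        plan = sorted(self.event_plan, key=lambda e: e.start_s)
        for ev in plan:
            if ev.start_s < 0 or ev.end_s > total_s:
                raise ValueError(
                    f"event at {ev.start_s:.1f}s extends outside the recording"
                )
            if ev.duration_s < self.min_event_duration_s:
                raise ValueError(
                    f"event duration {ev.duration_s:.1f}s below minimum "
                    f"{self.min_event_duration_s:.1f}s"
                )
        for a, b in zip(plan, plan[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"planned events overlap at {b.start_s:.1f}s"
                )


def random_event_plan(
    n_events: int,
    duration_h: float,
    rng: np.random.Generator,
    *,
    type_probs: dict[str, float] | None = None,
    reduction_range: tuple[float, float] = (0.5, 1.0),
    min_gap_s: float = 30.0,
    margin_s: float = 120.0,
) -> list[PlannedEvent]:
    """Draw a non-overlapping plan of respiratory events.

    Per-type durations are exponential above the 10 s scoring minimum with
    means matching :data:`TYPE_MEAN_DURATION_S`; the obstructive type
    dominates by default, as in clinical cohorts.
    """
    if type_probs is None:
        type_probs = {
            "ObstructiveApnea": 0.574,
            "CentralApnea": 0.036,
            "MixedApnea": 0.115,
            "Hypopnea": 0.275,
        }
    types = list(type_probs)
    probs = np.array([type_probs[t] for t in types], dtype=float)
    probs /= probs.sum()
    total_s = duration_h * 3600.0
    usable = total_s - 2 * margin_s
    if usable <= 0:
        raise ValueError("recording too short for the requested margins")
    events: list[PlannedEvent] = []
    t = margin_s + rng.uniform(0, min_gap_s)
    for _ in range(n_events):
        etype = types[rng.choice(len(types), p=probs)]
        dur = min(
            MIN_EVENT_DURATION_S
            + rng.exponential(TYPE_MEAN_DURATION_S[etype] - MIN_EVENT_DURATION_S),
            MAX_EVENT_DURATION_S,
        )
        if t + dur > total_s - margin_s:
            break
        red = rng.uniform(*reduction_range)
        events.append(
            PlannedEvent(
                type=etype,
                start_s=round(t, 2),
                duration_s=round(dur, 2),
                reduction_cannula=round(red, 3),
                reduction_thermistor=round(min(1.0, red + rng.uniform(-0.05, 0.05)), 3),
                residual_breathing=(etype == "Hypopnea"),
            )
        )
        t += dur + min_gap_s + rng.exponential(min_gap_s)
    return events


def _raised_cosine_breath(t: np.ndarray, f: float) -> np.ndarray:
    """Zero-mean inhale/exhale burst train with fundamental ``f`` (Hz)."""
    phase = np.mod(t * f, 1.0)
    w = np.zeros_like(t)
    inhale = phase < 0.35
    w[inhale] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[inhale] / 0.35))
    exhale = (phase >= 0.40) & (phase < 0.80)
    w[exhale] = -0.45 * (1.0 - np.cos(2.0 * np.pi * (phase[exhale] - 0.40) / 0.40))
    return w


def _default_hypnogram(n_epochs: int) -> list[str]:
    # Wake at lights-on, then repeating NREM/REM cycling; deterministic.
    cycle = ["N1", "N2", "N2", "N2", "N3", "N3", "N3", "N2", "N2", "R", "R", "W"]
    plan = ["W", "W", "W", "W"]
    i = 0
    while len(plan) < n_epochs:
        plan.append(cycle[i % len(cycle)])
        i += 1
    return plan[:n_epochs]


def _event_modulation(
    t: np.ndarray,
    plan: list[PlannedEvent],
    which: str,
    f: float,
) -> np.ndarray:
    """Flow waveform with the event plan applied for one sensor."""
    w = _raised_cosine_breath(t, f)
    for ev in plan:
        red = ev.reduction_cannula if which == "cannula" else ev.reduction_thermistor
        sl = slice(
            int(round(ev.start_s * _fs_of(t))),
            int(round(ev.end_s * _fs_of(t))),
        )
        if ev.residual_breathing:
            w[sl] = w[sl] * (1.0 - red)
        else:
            w[sl] = (1.0 - red) * np.sin(2.0 * np.pi * _WANDER_HZ * t[sl])
    return w


def _fs_of(t: np.ndarray) -> float:
    return 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0


def _breathing_loudness(t: np.ndarray, plan: list[PlannedEvent], f: float) -> np.ndarray:
    """Audio loudness profile: breath bursts, silenced inside events."""
    m = np.abs(_raised_cosine_breath(t, f))
    fs = _fs_of(t)
    for ev in plan:
        red = min(ev.reduction_cannula, ev.reduction_thermistor)
        sl = slice(int(round(ev.start_s * fs)), int(round(ev.end_s * fs)))
        m[sl] *= 1.0 - red
    return 0.1 + 0.9 * m


def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    x = rng.standard_normal(n).astype(np.float32)
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfilt(sos, x).astype(np.float32)
    y /= max(float(np.std(y)), 1e-12)
    return y


def _make_flow_channel(
    key: str, cfg: SimulationConfig, which: str, rng: np.random.Generator
) -> Signal:
    spec = spec_for(key)
    n = int(round(cfg.duration_h * 3600.0 * spec.fs))
    t = np.arange(n) / spec.fs
    w = _event_modulation(t, cfg.event_plan, which, cfg.breathing_rate_hz)
    a = cfg.breathing_amplitude
    samples = a * w + a * cfg.noise_level * rng.standard_normal(n)
    return Signal(key, samples, spec.fs, spec.physical_min, spec.physical_max,
                  spec.digital_min, spec.digital_max)


def _make_spo2(cfg: SimulationConfig, rng: np.random.Generator) -> Signal:
    spec = spec_for("SpO2")
    n = int(round(cfg.duration_h * 3600.0 * spec.fs))
    t = np.arange(n) / spec.fs
    s = cfg.spo2_baseline + 0.2 * rng.standard_normal(n)
    for ev in cfg.event_plan:
        if not ev.with_desat:
            continue
        t0 = ev.start_s + cfg.desat_lag_s
        # smooth raised-cosine dip of the configured depth and duration
        dip = cfg.desat_depth * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * np.clip((t - t0) / cfg.desat_duration_s, 0, 1))
        )
        s -= np.where((t >= t0) & (t < t0 + cfg.desat_duration_s), dip, 0.0)
    s = np.clip(s, cfg.spo2_floor, 100.0)
    return Signal("SpO2", s, spec.fs, spec.physical_min, spec.physical_max,
                  spec.digital_min, spec.digital_max)


def _make_audio_channel(
    key: str, cfg: SimulationConfig, rng: np.random.Generator
) -> Signal:
    spec = spec_for(key)
    n = int(round(cfg.duration_h * 3600.0 * spec.fs))
    t = (np.arange(n) / spec.fs).astype(np.float64)
    loud = _breathing_loudness(t, cfg.event_plan, cfg.breathing_rate_hz)
    band = {
        "Snore": (20.0, 200.0),
        "Tracheal": (350.0, 8000.0),     # contact microphone passband
        "Microphone": (100.0, 8000.0),
    }[key]
    carrier = _bandlimited_noise(n, spec.fs, band, rng)
    a = 30.0  # a.u. within the ±100 physical range
    samples = (a * loud).astype(np.float32) * carrier
    samples += np.float32(a * cfg.noise_level) * rng.standard_normal(n).astype(np.float32)
    return Signal(key, samples, spec.fs, spec.physical_min, spec.physical_max,
                  spec.digital_min, spec.digital_max)


def _make_aux_channel(key: str, cfg: SimulationConfig, rng: np.random.Generator) -> Signal:
    spec = spec_for(key)
    n = int(round(cfg.duration_h * 3600.0 * spec.fs))
    span = spec.physical_max - spec.physical_min
    if key == "Body":
        samples = np.full(n, 83.0)  # constant supine code
    elif key == "PulseRate":
        samples = 68.0 + 3.0 * rng.standard_normal(n)
    elif key == "RR":
        samples = 60.0 + 2.0 * rng.standard_normal(n)
    else:
        # noise placeholder at a physiological-looking fraction of the range
        samples = 0.05 * span * rng.standard_normal(n)
    samples = np.clip(samples, spec.physical_min, spec.physical_max)
    return Signal(key, samples, spec.fs, spec.physical_min, spec.physical_max,
                  spec.digital_min, spec.digital_max)


def generate_study(config: SimulationConfig) -> Study:
    """Render a full synthetic :class:`~somnoscore.types.Study`.

    Deterministic for a fixed config (same seed ⇒ bit-identical arrays).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # resolve per-event desat/arousal flags (None ⇒ Bernoulli draw)
    plan: list[PlannedEvent] = []
    for ev in sorted(config.event_plan, key=lambda e: e.start_s):
        desat = ev.with_desat if ev.with_desat is not None else bool(
            rng.random() < config.desat_prob
        )
        arousal = ev.with_arousal if ev.with_arousal is not None else bool(
            rng.random() < config.arousal_prob
        )
        plan.append(
            PlannedEvent(
                ev.type, ev.start_s, ev.duration_s, ev.reduction_cannula,
                ev.reduction_thermistor, ev.residual_breathing, desat, arousal,
            )
        )
    cfg = replace(config, event_plan=plan)

    channels: dict[str, Signal] = {}
    for key in FLOW_KEYS:
        which = "cannula" if key == "Flow Patient" else "thermistor"
        channels[key] = _make_flow_channel(key, cfg, which, rng)
    channels["SpO2"] = _make_spo2(cfg, rng)
    for key in cfg.audio_channels:
        channels[key] = _make_audio_channel(key, cfg, rng)
    for key in cfg.aux_channels:
        if key not in channels:
            channels[key] = _make_aux_channel(key, cfg, rng)

    n_epochs = int(np.ceil(cfg.duration_h * 3600.0 / cfg.epoch_s))
    stages = cfg.hypnogram_plan or _default_hypnogram(n_epochs)
    if len(stages) != n_epochs:
        raise ValueError(
            f"hypnogram_plan has {len(stages)} epochs; recording needs {n_epochs}"
        )
    hypnogram = list(enumerate(stages))

    events: list[EventAnnotation] = []
    total_s = cfg.duration_h * 3600.0
    for ev in plan:
        events.append(EventAnnotation("Respiratory", ev.type, ev.start_s, ev.duration_s))
        if ev.with_desat:
            t0 = ev.start_s + cfg.desat_lag_s
            if t0 + cfg.desat_duration_s <= total_s:
                events.append(
                    EventAnnotation("SpO2", "RelativeDesaturation", t0, 15.0)
                )
        if ev.with_arousal:
            t0 = ev.end_s + cfg.arousal_lag_s
            if t0 + cfg.arousal_duration_s <= total_s:
                events.append(
                    EventAnnotation("Neurological", "Arousal", t0, cfg.arousal_duration_s)
                )
    events.sort(key=lambda e: e.start_s)

    return Study(
        patient_id=cfg.patient_id,
        age=cfg.age,
        gender=cfg.gender,
        channels=channels,
        hypnogram=hypnogram,
        events=events,
        epoch_s=cfg.epoch_s,
        recording_time_h=cfg.duration_h,
    )


def render_device_pair(study: Study, offset_s: float) -> tuple[Signal, Signal]:
    """Simulate the two separately started recorders.

    Returns the PSG's built-in 500 Hz ``Snore`` channel (clock origin of the
    study) and the separately recorded 48 kHz high-quality tracheal audio
    whose recording starts ``offset_s`` seconds AFTER the PSG (negative:
    before; the pre-PSG part is silence-level noise).
    """
    if study.duration_s <= 0:
        raise ValueError("study has zero duration")
    if abs(offset_s) >= study.duration_s:
        raise ValueError("|offset_s| must be smaller than the study duration")
    if "Snore" not in study.channels or "Tracheal" not in study.channels:
        raise ValueError("study must carry 'Snore' and 'Tracheal' channels")
    snore = study.channels["Snore"]
    tracheal = study.channels["Tracheal"]
    fs = tracheal.fs
    if offset_s >= 0:
        samples = tracheal.samples[int(round(offset_s * fs)):]
    else:
        pad = np.zeros(int(round(-offset_s * fs)), dtype=tracheal.samples.dtype)
        samples = np.concatenate([pad, tracheal.samples])
    hq = Signal("Tracheal", samples, fs, tracheal.physical_min,
                tracheal.physical_max, tracheal.digital_min, tracheal.digital_max)
    return snore, hq


__all__ = [
    "AUDIO_CHANNELS",
    "AUX_CHANNELS",
    "MAX_EVENT_DURATION_S",
    "PlannedEvent",
    "SimulationConfig",
    "TYPE_MEAN_DURATION_S",
    "generate_study",
    "random_event_plan",
    "render_device_pair",
]
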