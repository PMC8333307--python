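"""Automatic screening of scored apnea/hypopnea events against flow criteria.

Scorers reading flow-rate traces by eye tend to err toward positives when the
amplitude reduction is near the 30 % scoring threshold, so annotated event
lists carry false positives.  This module re-examines every scored
respiratory event against the two nasal airflow sensors (pressure cannula
and thermistor):

* The flow envelope is extracted by Hilbert transform, with excursions
  shorter than 3 s suppressed (morphological closing/opening), so brief
  dropouts or single missed breaths do not masquerade as events.
* Normal-breathing amplitude is the envelope maximum over the 5 s frames
  immediately before and after the event; the reduction is one minus the
  ratio of the in-event envelope minimum to that baseline.
* An event must show at least a 30 % reduction on BOTH usable sensors; a
  reduction seen by only one sensor marks the event as a false positive.
* A sensor whose local amplitude is at noise level (e.g. temporarily
  dislocated) is excluded from the investigation entirely.
* Optionally, rejection additionally requires the in-event flow to keep a
  dominant frequency inside the normal breathing band (0.16–0.4 Hz, a breath
  every 3–5 s guard): reduced-but-disturbed breathing is then not rejected.

Accepted events can be re-emitted as a "clean" annotation file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps
from scipy.fft import next_fast_len

from .channels import FLOW_KEYS
from .scoring import classify_severity, total_sleep_time
from .types import EventAnnotation, Signal, Study


@dataclass(frozen=True)
class ValidationParams:
    """Tunable thresholds of the screening rule."""

    min_reduction: float = 0.30          # dual-sensor amplitude criterion
    baseline_window_s: float = 5.0       # normal-breathing frames around the event
    min_change_duration_s: float = 3.0   # envelope excursions shorter than this are ignored
    breathing_band_hz: tuple[float, float] = (0.16, 0.4)
    envelope_smooth_hz: float | None = 1.0  # low-pass on the Hilbert magnitude
    noise_floor: float = 0.05            # fraction of channel-wide envelope median
    abs_noise_floor: float = 0.05        # fraction of the physical half-range
    require_both_sensors: bool = True
    frequency_rule_enabled: bool = True
    exclude_neighbor_events: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.min_reduction < 1.0:
            raise ValueError("min_reduction must lie in (0, 1)")
        lo, hi = self.breathing_band_hz
        if not lo < hi:
            raise ValueError("breathing band lower bound must be below the upper")


class ChannelUnusable(Exception):
    """The sensor's local amplitude is at noise level; exclude the channel."""


@dataclass(frozen=True)
class EventVerdict:
    event: EventAnnotation
    accepted: bool
    reduction_cannula: float | None      # None: channel unusable for this event
    reduction_thermistor: float | None
    dominant_freq_hz: float | None
    reason: str | None                   # rejection cause; None when accepted
    indeterminate: bool = False          # accepted only because no sensor was usable

    def to_dict(self) -> dict:
        return {
            "type": self.event.type,
            "start_s": self.event.start_s,
            "duration_s": self.event.duration_s,
            "accepted": self.accepted,
            "reduction_cannula": self.reduction_cannula,
            "reduction_thermistor": self.reduction_thermistor,
            "dominant_freq_hz": self.dominant_freq_hz,
            "reason": self.reason,
            "indeterminate": self.indeterminate,
        }


@dataclass
class ValidationReport:
    verdicts: list[EventVerdict] = field(default_factory=list)
    ahi_before: float = 0.0
    ahi_after: float = 0.0
    severity_before: str = "Normal"
    severity_after: str = "Normal"

    @property
    def n_rejected(self) -> int:
        return sum(1 for v in self.verdicts if not v.accepted)

    @property
    def rejected_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.verdicts:
            if not v.accepted:
                out[v.event.type] = out.get(v.event.type, 0) + 1
        return out

    @property
    def accepted_events(self) -> list[EventAnnotation]:
        return [v.event for v in self.verdicts if v.accepted]

    def to_dict(self) -> dict:
        return {
            "n_events": len(self.verdicts),
            "n_rejected": self.n_rejected,
            "rejected_by_type": self.rejected_by_type,
            "ahi_before": self.ahi_before,
            "ahi_after": self.ahi_after,
            "severity_before": self.severity_before,
            "severity_after": self.severity_after,
            "verdicts": [v.to_dict() for v in self.verdicts],
        }


def flow_envelope(flow: Signal, params: ValidationParams | None = None) -> Signal:
    """Hilbert envelope with sub-3 s excursions suppressed.

    Grey-scale closing (fills dips shorter than the horizon — the gaps
    between breath bursts and brief dropouts) followed by opening (removes
    equally short bumps) on the analytic magnitude.
    """
    params = params or ValidationParams()
    x = np.asarray(flow.samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty flow signal")
    if flow.fs < 10:
        raise ValueError("flow sampling rate below 10 Hz")
    env = np.abs(sps.hilbert(x, N=next_fast_len(x.size))[: x.size])
    if params.envelope_smooth_hz and params.envelope_smooth_hz < 0.5 * flow.fs:
        # suppress broadband noise ripple so the morphology tracks breathing
        sos = sps.butter(4, params.envelope_smooth_hz, btype="low",
                         fs=flow.fs, output="sos")
        env = np.maximum(sps.sosfiltfilt(sos, env), 0.0)
    n = int(round(params.min_change_duration_s * flow.fs))
    if n >= 2:
        env = ndimage.grey_closing(env, size=n, mode="nearest")
        env = ndimage.grey_opening(env, size=n, mode="nearest")
    return Signal(flow.label, env, flow.fs, flow.physical_min, flow.physical_max,
                  flow.digital_min, flow.digital_max)


def _window_samples(
    envelope: Signal,
    event: EventAnnotation,
    params: ValidationParams,
    others: list[EventAnnotation] | None,
) -> np.ndarray:
    w = params.baseline_window_s
    pre = envelope.time_slice(event.start_s - w, event.start_s)
    post = envelope.time_slice(event.end_s, event.end_s + w)
    if params.exclude_neighbor_events and others:
        pre = _mask_events(pre, event.start_s - w, envelope.fs, others)
        post = _mask_events(post, event.end_s, envelope.fs, others)
    return np.concatenate([pre, post])


def _mask_events(seg, t0, fs, others):
    if seg.size == 0:
        return seg
    t = t0 + np.arange(seg.size) / fs
    keep = np.ones(seg.size, dtype=bool)
    for o in others:
        keep &= ~((t >= o.start_s) & (t < o.end_s))
    return seg[keep]


def baseline_amplitude(
    envelope: Signal,
    event: EventAnnotation,
    params: ValidationParams | None = None,
    others: list[EventAnnotation] | None = None,
) -> float:
    """Maximum envelope amplitude over the 5 s frames framing the event."""
    params = params or ValidationParams()
    win = _window_samples(envelope, event, params, others)
    if win.size == 0:
        raise ValueError(
            f"no baseline samples around event at {event.start_s:.1f}s"
        )
    return float(win.max())


def reduction_fraction(
    envelope: Signal, event: EventAnnotation, baseline: float
) -> float:
    """1 − (in-event envelope minimum / baseline), clipped to [0, 1]."""
    if baseline <= 0:
        raise ValueError("baseline amplitude must be positive")
    inside = envelope.time_slice(event.start_s, event.end_s)
    if inside.size == 0:
        raise ValueError(f"event at {event.start_s:.1f}s contains no samples")
    return float(np.clip(1.0 - inside.min() / baseline, 0.0, 1.0))


def channel_usable(
    envelope: Signal, baseline: float, params: ValidationParams | None = None
) -> bool:
    """Whether the sensor carries signal (vs noise) around this event.

    The baseline must clear both a relative floor (fraction of the
    channel-wide envelope median, catching locally dislocated sensors) and
    an absolute floor (fraction of the physical half-range, catching sensors
    that were flat noise for the whole recording).
    """
    params = params or ValidationParams()
    median = float(np.median(envelope.samples))
    half_range = 0.5 * (envelope.physical_max - envelope.physical_min)
    floor = max(params.noise_floor * median, params.abs_noise_floor * half_range)
    return baseline >= floor


def dominant_frequency(
    flow: Signal, event: EventAnnotation, max_hz: float = 1.0
) -> float | None:
    """Spectral peak (Hz) of the detrended in-event flow, or None if silent.

    Detrended periodogram with a Hann window, zero-padded for peak
    interpolation; resolution is limited by the event duration.
    """
    seg = np.asarray(flow.time_slice(event.start_s, event.end_s), dtype=np.float64)
    if seg.size < 4 or np.allclose(seg, 0.0):
        return None
    seg = sps.detrend(seg)
    nfft = next_fast_len(max(seg.size * 4, int(flow.fs * 64)))
    freqs, pxx = sps.periodogram(seg, fs=flow.fs, window="hann", nfft=nfft)
    band = (freqs > 0) & (freqs <= max_hz)
    if not band.any() or not np.any(pxx[band] > 0):
        return None
    fb, pb = freqs[band], pxx[band]
    return float(fb[int(np.argmax(pb))])


def _examine_channel(
    flow: Signal,
    env: Signal,
    event: EventAnnotation,
    params: ValidationParams,
    others: list[EventAnnotation] | None,
) -> float:
    """Reduction fraction on one sensor; raises ChannelUnusable at noise level."""
    baseline = baseline_amplitude(env, event, params, others)
    if not channel_usable(env, baseline, params):
        raise ChannelUnusable(flow.label)
    return reduction_fraction(env, event, baseline)


def validate_events(
    study: Study, params: ValidationParams | None = None
) -> ValidationReport:
    """Screen every scored respiratory event of the study.

    Rejection requires the amplitude criterion to fail on a usable sensor
    AND — when the breathing-rate rule is enabled — an in-band dominant
    frequency confirming ongoing normal-rate breathing.  Events with no
    usable sensor are accepted but flagged indeterminate (screening errs
    toward positives, as the scoring clinicians do).
    """
    params = params or ValidationParams()
    missing = [k for k in FLOW_KEYS if k not in study.channels]
    if missing:
        raise ValueError(f"study lacks flow channels: {missing}")
    flows = {k: study.channels[k] for k in FLOW_KEYS}
    envs = {k: flow_envelope(sig, params) for k, sig in flows.items()}

    resp = study.respiratory_events
    others_all = resp if params.exclude_neighbor_events else None

    verdicts: list[EventVerdict] = []
    for event in resp:
        others = (
            [o for o in others_all if o is not event] if others_all else None
        )
        reductions: dict[str, float | None] = {}
        for key in FLOW_KEYS:
            try:
                reductions[key] = _examine_channel(
                    flows[key], envs[key], event, params, others
                )
            except ChannelUnusable:
                reductions[key] = None

        usable = {k: r for k, r in reductions.items() if r is not None}
        dom_freq: float | None = None
        if not usable:
            verdicts.append(EventVerdict(
                event, True, reductions[FLOW_KEYS[0]], reductions[FLOW_KEYS[1]],
                None, None, indeterminate=True,
            ))
            continue

        failing = [k for k, r in usable.items() if r < params.min_reduction]
        if params.require_both_sensors:
            amplitude_fails = bool(failing)
        else:
            amplitude_fails = len(failing) == len(usable)

        rejected = False
        if amplitude_fails:
            if params.frequency_rule_enabled:
                lo, hi = params.breathing_band_hz
                for key in usable:
                    f = dominant_frequency(flows[key], event)
                    if f is not None and dom_freq is None:
                        dom_freq = f
                    if f is not None and lo <= f <= hi:
                        dom_freq = f
                        rejected = True
                        break
            else:
                rejected = True
        reason = "insufficient-reduction" if rejected else None
        verdicts.append(EventVerdict(
            event, not rejected, reductions[FLOW_KEYS[0]], reductions[FLOW_KEYS[1]],
            dom_freq, reason,
        ))

    tst_h = total_sleep_time(study.hypnogram, study.epoch_s)
    denom = tst_h if tst_h > 0 else study.recording_time_h
    n_before = len(resp)
    n_after = sum(1 for v in verdicts if v.accepted)
    ahi_before = n_before / denom if denom > 0 else 0.0
    ahi_after = n_after / denom if denom > 0 else 0.0
    return ValidationReport(
        verdicts=verdicts,
        ahi_before=ahi_before,
        ahi_after=ahi_after,
        severity_before=classify_severity(ahi_before),
        severity_after=classify_severity(ahi_after),
    )


__all__ = [
    "ChannelUnusable",
    "EventVerdict",
    "ValidationParams",
    "ValidationReport",
    "baseline_amplitude",
    "channel_usable",
    "dominant_frequency",
    "flow_envelope",
    "reduction_fraction",
    "validate_events",
]
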