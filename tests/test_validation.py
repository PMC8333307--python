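"""Screening of annotated events against the flow-amplitude criteria."""

import numpy as np
import pytest

from somnoscore.synthetic import PlannedEvent, SimulationConfig, generate_study
from somnoscore.types import EventAnnotation, Signal, Study
from somnoscore.validation import (
    ValidationParams,
    baseline_amplitude,
    channel_usable,
    dominant_frequency,
    flow_envelope,
    reduction_fraction,
    validate_events,
)
from conftest import planted_truth_study

FS = 100.0


def _flow_sig(samples, label="Flow Patient"):
    return Signal(label, np.asarray(samples, dtype=float), FS)


def _event(start, dur, etype="ObstructiveApnea"):
    return EventAnnotation("Respiratory", etype, start, dur)


def _breathing(n_s, f=0.25, a=50.0):
    t = np.arange(int(n_s * FS)) / FS
    return a * np.sin(2 * np.pi * f * t)


class TestFlowEnvelope:
    def test_steady_breathing_gives_flat_envelope(self):
        env = flow_envelope(_flow_sig(_breathing(120))).samples
        mid = env[int(10 * FS): -int(10 * FS)]
        assert np.ptp(mid) / np.median(mid) < 0.15

    def test_short_dropout_is_ignored(self):
        # a 1 s cessation (< 3 s) must not dent the suppressed envelope
        x = _breathing(120)
        x[int(60 * FS): int(61 * FS)] = 0.0
        env_clean = flow_envelope(_flow_sig(_breathing(120))).samples
        env_drop = flow_envelope(_flow_sig(x)).samples
        win = slice(int(55 * FS), int(66 * FS))
        assert np.abs(env_drop[win] - env_clean[win]).max() < 0.15 * np.median(env_clean)

    def test_long_cessation_shows_in_envelope(self):
        x = _breathing(120)
        x[int(50 * FS): int(70 * FS)] = 0.0
        env = flow_envelope(_flow_sig(x)).samples
        inside = env[int(55 * FS): int(65 * FS)]
        assert inside.max() < 0.15 * np.median(env[: int(40 * FS)])

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            flow_envelope(_flow_sig([]))


class TestBaselineAmplitude:
    def test_constant_envelope_returns_constant(self):
        env = _flow_sig(np.full(int(60 * FS), 7.25))
        assert baseline_amplitude(env, _event(30, 10)) == pytest.approx(7.25)

    def test_max_over_pre_and_post_windows(self):
        # direct max oracle: pre-window peaks at 8, post-window at 6
        samples = np.full(int(60 * FS), 1.0)
        samples[int(26 * FS)] = 8.0   # inside [25, 30) pre-window
        samples[int(41 * FS)] = 6.0   # inside [40, 45) post-window
        env = _flow_sig(samples)
        assert baseline_amplitude(env, _event(30, 10)) == 8.0

    def test_event_at_recording_start_uses_post_window(self):
        samples = np.full(int(30 * FS), 1.0)
        samples[int(12 * FS)] = 4.0  # post-window [10, 15)
        env = _flow_sig(samples)
        assert baseline_amplitude(env, _event(0, 10)) == 4.0


class TestReductionFraction:
    def test_silent_event_is_full_reduction(self):
        samples = np.ones(int(60 * FS))
        samples[int(20 * FS): int(40 * FS)] = 0.0
        assert reduction_fraction(_flow_sig(samples), _event(20, 20), 1.0) == 1.0

    def test_threshold_arithmetic(self):
        samples = np.full(int(60 * FS), 7.0)
        assert reduction_fraction(_flow_sig(samples), _event(20, 20), 10.0) == pytest.approx(0.30)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            reduction_fraction(_flow_sig(np.ones(6000)), _event(20, 20), 0.0)

    @pytest.mark.parametrize("planned", [0.2, 0.5, 0.9])
    def test_generator_reduction_recovered(self, planned):
        # exact recovery on the residual-breathing surface: the reduced
        # oscillation encodes the planned fraction in its envelope
        ev = PlannedEvent("Hypopnea", 120, 20, planned, planned,
                          residual_breathing=True)
        cfg = SimulationConfig(duration_h=300 / 3600, seed=9, noise_level=0.05,
                               event_plan=[ev], audio_channels=(), aux_channels=())
        study = generate_study(cfg)
        env = flow_envelope(study.channels["Flow Patient"])
        b = baseline_amplitude(env, study.respiratory_events[0])
        r = reduction_fraction(env, study.respiratory_events[0], b)
        assert r == pytest.approx(planned, abs=0.05)

    def test_cessation_reduction_bounded_from_below(self):
        # without residual oscillation the envelope can only bound the
        # planned reduction from below (the wander's minima dominate)
        ev = PlannedEvent("ObstructiveApnea", 120, 20, 0.9, 0.9,
                          residual_breathing=False)
        cfg = SimulationConfig(duration_h=300 / 3600, seed=9, noise_level=0.05,
                               event_plan=[ev], audio_channels=(), aux_channels=())
        study = generate_study(cfg)
        env = flow_envelope(study.channels["Flow Patient"])
        b = baseline_amplitude(env, study.respiratory_events[0])
        r = reduction_fraction(env, study.respiratory_events[0], b)
        assert r >= 0.85


class TestDominantFrequency:
    def test_tone_frequency_recovered(self):
        assert dominant_frequency(
            _flow_sig(_breathing(120, f=0.25)), _event(30, 40)
        ) == pytest.approx(0.25, abs=0.03)

    def test_zero_segment_undefined(self):
        assert dominant_frequency(_flow_sig(np.zeros(int(60 * FS))), _event(20, 20)) is None

    def test_subsonic_wander_outside_breathing_band(self):
        t = np.arange(int(120 * FS)) / FS
        slow = 5.0 * np.sin(2 * np.pi * 0.07 * t)
        f = dominant_frequency(_flow_sig(slow), _event(30, 40))
        assert f is not None and not (0.16 <= f <= 0.4)


class TestValidateEvents:
    def _study(self, plan, seed=0, **kw):
        cfg = SimulationConfig(
            duration_h=max(e.end_s for e in plan) / 3600 + 0.05,
            seed=seed, event_plan=plan, audio_channels=(), aux_channels=(), **kw)
        return generate_study(cfg)

    def test_strong_dual_sensor_reduction_accepted(self):
        st = self._study([PlannedEvent("ObstructiveApnea", 100, 20, 0.9, 0.9)])
        rep = validate_events(st)
        assert rep.verdicts[0].accepted

    def test_subthreshold_with_residual_breathing_rejected(self):
        st = self._study([PlannedEvent("Hypopnea", 100, 20, 0.2, 0.2, True)])
        rep = validate_events(st)
        v = rep.verdicts[0]
        assert not v.accepted
        assert v.reason == "insufficient-reduction"
        assert 0.16 <= v.dominant_freq_hz <= 0.4

    def test_single_sensor_reduction_is_false_positive(self):
        st = self._study([PlannedEvent("Hypopnea", 100, 20, 0.5, 0.1, True)])
        rep = validate_events(st)
        assert not rep.verdicts[0].accepted

    def test_unusable_thermistor_excluded_from_investigation(self):
        st = self._study([PlannedEvent("ObstructiveApnea", 100, 20, 0.5, 0.5)])
        # replace the thermistor with all-night flat noise (dislocated sensor)
        therm = st.channels["Flow Patient 2"]
        rng = np.random.default_rng(0)
        st.channels["Flow Patient 2"] = Signal(
            therm.label, 1.0 * rng.standard_normal(therm.n_samples), therm.fs,
            therm.physical_min, therm.physical_max,
            therm.digital_min, therm.digital_max)
        rep = validate_events(st)
        v = rep.verdicts[0]
        assert v.accepted
        assert v.reduction_thermistor is None
        assert v.reduction_cannula == pytest.approx(0.5, abs=0.07)

    def test_both_sensors_unusable_is_indeterminate_accepted(self):
        st = self._study([PlannedEvent("ObstructiveApnea", 100, 20, 0.5, 0.5)])
        rng = np.random.default_rng(0)
        for key in ("Flow Patient", "Flow Patient 2"):
            ch = st.channels[key]
            st.channels[key] = Signal(ch.label, 1.0 * rng.standard_normal(ch.n_samples),
                                      ch.fs, ch.physical_min, ch.physical_max,
                                      ch.digital_min, ch.digital_max)
        rep = validate_events(st)
        assert rep.verdicts[0].accepted
        assert rep.verdicts[0].indeterminate

    def test_missing_flow_channels_rejected(self):
        study = Study(patient_id=1, age=50, gender="M", hypnogram=[(0, "N2")],
                      events=[_event(10, 20)], recording_time_h=0.5)
        with pytest.raises(ValueError, match="flow channels"):
            validate_events(study)

    def test_raising_threshold_never_accepts_more(self):
        st, _ = planted_truth_study(3, n_true=10, n_false=10)
        n_prev = None
        for thr in (0.1, 0.3, 0.5, 0.7):
            rep = validate_events(st, ValidationParams(min_reduction=thr))
            n_acc = sum(v.accepted for v in rep.verdicts)
            if n_prev is not None:
                assert n_acc <= n_prev
            n_prev = n_acc

    def test_report_is_deterministic_and_consistent(self):
        st, _ = planted_truth_study(5, n_true=5, n_false=5)
        r1 = validate_events(st)
        r2 = validate_events(st)
        assert [v.accepted for v in r1.verdicts] == [v.accepted for v in r2.verdicts]
        assert r1.n_rejected == sum(1 for v in r1.verdicts if not v.accepted)
        assert sum(r1.rejected_by_type.values()) == r1.n_rejected
        assert r1.ahi_after <= r1.ahi_before
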