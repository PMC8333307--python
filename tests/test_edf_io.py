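"""EDF/RML/WAV round trips, 24->16-bit quantization, 1-hour cropping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnoscore import edf_io
from somnoscore.channels import CHANNEL_TABLE
from somnoscore.edf_io import (
    EDFError,
    crop_hours,
    physical_to_int24,
    quantize_24_to_16,
    read_edf,
    read_rml,
    read_wav24,
    write_edf,
    write_rml,
    write_wav24,
)
from somnoscore.edf_io import _phys_to_dig
from somnoscore.types import EventAnnotation, Signal, Study, TaxonomyError


class TestQuantize:
    def test_zero_is_lossless(self):
        s16, stats = quantize_24_to_16(np.array([0], dtype=np.int32))
        assert s16[0] == 0 and stats.max_abs == 0.0

    def test_255_truncates_to_zero(self):
        # direct integer arithmetic: 255 >> 8 == 0, error 255/2^24
        s16, stats = quantize_24_to_16(np.array([255], dtype=np.int32))
        assert s16[0] == 0
        assert stats.max_abs == pytest.approx(255 / 2**24)

    def test_negative_truncation_rounds_toward_minus_inf(self):
        s16, _ = quantize_24_to_16(np.array([-1, -256, -257], dtype=np.int32))
        assert list(s16) == [-1, -1, -2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quantize_24_to_16(np.array([2**23], dtype=np.int64))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(-(2**23), 2**23 - 1), min_size=1, max_size=200))
    def test_error_bounded_and_lossless_on_clean_low_byte(self, values):
        s24 = np.array(values, dtype=np.int64)
        s16, stats = quantize_24_to_16(s24)
        err = s24 - (s16.astype(np.int64) << 8)
        assert err.min() >= 0 and err.max() <= 255
        assert stats.max_abs <= 255 / 2**24
        clean = s24[s24 % 256 == 0]
        if clean.size:
            back = (quantize_24_to_16(clean)[0].astype(np.int64)) << 8
            assert np.array_equal(back, clean)


class TestWav:
    def test_wav24_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        s24 = rng.integers(-(2**23), 2**23, size=48000, dtype=np.int64).astype(np.int32)
        p = tmp_path / "t.wav"
        write_wav24(p, s24, 48000)
        back, fs = read_wav24(p)
        assert fs == 48000
        assert np.array_equal(back, s24)

    def test_physical_to_int24_spans_code_range(self):
        sig = Signal("Tracheal", np.array([-100.0, 0.0, 100.0]), 48000)
        codes = physical_to_int24(sig)
        assert codes[0] == -(2**23)
        assert codes[2] == 2**23 - 1
        assert abs(int(codes[1])) <= 1


class TestEdfRoundTrip:
    def test_digital_samples_recovered_bit_exactly(self, fixture_study, tmp_path):
        path = tmp_path / "fx.edf"
        write_edf(fixture_study, path)
        back = read_edf(path)
        assert set(back.channels) == set(fixture_study.channels)
        for key, sig in fixture_study.channels.items():
            d1 = _phys_to_dig(sig.samples, sig)
            d2 = _phys_to_dig(back.channels[key].samples[: sig.n_samples],
                              back.channels[key])
            assert np.array_equal(d1, d2), key
        assert back.patient_id == fixture_study.patient_id
        assert back.gender == fixture_study.gender

    def test_mne_reads_identical_physical_values(self, fixture_study, tmp_path):
        # independent EDF oracle: mne's reader must agree with ours
        mne = pytest.importorskip("mne")
        path = tmp_path / "fx.edf"
        write_edf(fixture_study, path)
        ours = read_edf(path)
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        snore = ours.channels["Snore"].samples
        theirs = raw.get_data(picks=[raw.ch_names.index("Snore")])[0]
        assert np.abs(theirs[: snore.size] - snore).max() < 1e-9

    def test_fs_mismatch_with_table_rejected(self, tmp_path):
        bad = Study(patient_id=1, age=50, gender="M", channels={
            "Snore": Signal("Snore", np.zeros(1000), 250.0)})
        with pytest.raises(ValueError, match="fs"):
            write_edf(bad, tmp_path / "bad.edf")

    def test_empty_study_rejected(self, tmp_path):
        empty = Study(patient_id=1, age=50, gender="M")
        with pytest.raises(ValueError):
            write_edf(empty, tmp_path / "empty.edf")

    def test_truncated_file_reports_byte_offset(self, fixture_study, tmp_path):
        path = tmp_path / "fx.edf"
        write_edf(fixture_study, path)
        data = path.read_bytes()
        (tmp_path / "trunc.edf").write_bytes(data[:100])
        with pytest.raises(EDFError, match="byte"):
            read_edf(tmp_path / "trunc.edf")

    def test_flow_only_edf_reads_two_channels(self, tmp_path):
        n = 100 * 60
        study = Study(patient_id=2, age=40, gender="F", channels={
            "Flow Patient": Signal("Flow Patient", np.zeros(n), 100.0),
            "Flow Patient 2": Signal("Flow Patient 2", np.ones(n), 100.0),
        })
        path = tmp_path / "flow.edf"
        write_edf(study, path)
        back = read_edf(path)
        assert set(back.channels) == {"Flow Patient", "Flow Patient 2"}


class TestCropHours:
    def _long_study(self, hours):
        # low-rate channels keep a multi-hour study cheap
        n = int(hours * 3600)
        channels = {
            "SpO2": Signal("SpO2", np.full(n, 96.0), 1.0, 0, 102.3, 0, 1023),
            "RR": Signal("RR", np.full(n, 60.0), 1.0, 0, 200, 0, 200),
        }
        events = [
            EventAnnotation("Respiratory", "ObstructiveApnea", 3599.5, 20.0),
            EventAnnotation("Respiratory", "Hypopnea", 10.0, 15.0),
            EventAnnotation("Respiratory", "Hypopnea", 2 * 3600 + 5.0, 15.0),
        ]
        n_ep = int(np.ceil(hours * 3600 / 30))
        hyp = [(i, "W" if i < 4 else "N2") for i in range(n_ep)]
        return Study(patient_id=1000, age=60, gender="M", channels=channels,
                     hypnogram=hyp, events=events, recording_time_h=hours)

    def test_three_and_a_half_hours_gives_four_parts(self):
        parts = crop_hours(self._long_study(3.5))
        assert len(parts) == 4
        assert [round(p.recording_time_h, 3) for p in parts] == [1, 1, 1, 0.5]

    def test_boundary_event_stays_global_in_first_part(self):
        parts = crop_hours(self._long_study(3.5))
        ev = [e for e in parts[0].events if e.type == "ObstructiveApnea"]
        assert len(ev) == 1 and ev[0].start_s == 3599.5  # not re-based

    def test_ten_minute_study_single_part(self, fixture_study):
        assert len(crop_hours(fixture_study)) == 1

    def test_concatenation_restores_samples_and_events(self):
        study = self._long_study(3.5)
        parts = crop_hours(study)
        for key in study.channels:
            cat = np.concatenate([p.channels[key].samples for p in parts])
            assert np.array_equal(cat, study.channels[key].samples)
        assert sum(len(p.events) for p in parts) == len(study.events)
        assert sum(len(p.hypnogram) for p in parts) == len(study.hypnogram)


class TestRml:
    def test_round_trip_identity(self, fixture_study, tmp_path):
        p = write_rml(fixture_study, tmp_path / "fx.rml")
        back = read_rml(p)
        assert back.events == fixture_study.events
        assert back.hypnogram == fixture_study.hypnogram
        assert (back.patient_id, back.age, back.gender) == (
            fixture_study.patient_id, fixture_study.age, fixture_study.gender)
        assert back.epoch_s == fixture_study.epoch_s

    def test_illegal_family_type_pair_rejected(self):
        with pytest.raises(TaxonomyError, match="Snore"):
            EventAnnotation("Cardiac", "Snore", 0.0, 5.0)

    def test_reader_names_offending_event(self, tmp_path):
        text = """<?xml version='1.0'?>
<PatientStudy schema_version="1">
  <Patient><Id>1</Id><Age>50</Age><Gender>M</Gender></Patient>
  <SleepStages EpochLength="30.0"><Stage Type="N2" Start="0.0"/></SleepStages>
  <Events><Event Family="Cardiac" Type="Snore" Start="5.0" Duration="3.0"/></Events>
</PatientStudy>"""
        p = tmp_path / "bad.rml"
        p.write_text(text)
        with pytest.raises(TaxonomyError, match="event #0"):
            read_rml(p)

    def test_empty_event_list_round_trips(self, tmp_path):
        study = Study(patient_id=1, age=30, gender="F",
                      hypnogram=[(0, "N2")], events=[])
        p = write_rml(study, tmp_path / "e.rml")
        assert read_rml(p).events == []

    def test_clean_flag_prefixes_filename_and_filters(self, fixture_study, tmp_path):
        resp = fixture_study.respiratory_events
        keep = resp[:2]
        p = write_rml(fixture_study, tmp_path / "fx.rml", clean=True, accepted=keep)
        assert p.name == "clean_fx.rml"
        back = read_rml(p)
        assert back.respiratory_events == sorted(keep, key=lambda e: e.start_s)
        # non-respiratory annotations (desats, arousals) are preserved
        n_other = len(fixture_study.events) - len(resp)
        assert len(back.events) == n_other + len(keep)

    def test_short_respiratory_event_rejected_when_strict(self, tmp_path):
        study = Study(patient_id=1, age=30, gender="M", hypnogram=[(0, "N2")],
                      events=[EventAnnotation("Respiratory", "Hypopnea", 0.0, 5.0)])
        with pytest.raises(ValueError, match="minimum"):
            write_rml(study, tmp_path / "s.rml")
        write_rml(study, tmp_path / "s.rml", strict_durations=False)
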