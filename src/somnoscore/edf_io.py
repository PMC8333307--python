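"""On-disk representation of a study: EDF, 24-bit WAV and RML annotations.

The dataset dialect is plain 16-bit EDF with 1 s data records and the fixed
channel table of :mod:`somnoscore.channels`.  Separately recorded 24-bit WAV
audio is converted to 16 bits by truncating the least significant byte before
it enters an EDF.  Annotations travel in an RML-style XML sidecar carrying
patient age/gender, the sleep-stage sequence and the event list; recordings
are cropped into 1-hour EDF parts for handling, with event timestamps kept
global (seconds from recording start) so association windows remain
well-defined across part boundaries.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .channels import CHANNEL_TABLE, ChannelSpec, spec_for
from .types import (
    EventAnnotation,
    MIN_EVENT_DURATION_S,
    RESPIRATORY_SCORED_TYPES,
    Signal,
    Study,
    TaxonomyError,
)

FULL_SCALE_24 = 2**24
INT24_MIN, INT24_MAX = -(2**23), 2**23 - 1


class EDFError(ValueError):
    """Malformed EDF content; the message carries the byte offset."""


# ---------------------------------------------------------------------------
# 24 -> 16 bit audio conversion


@dataclass(frozen=True)
class ConversionErrorStats:
    """Truncation error statistics, as fractions of the 24-bit full scale."""

    mean_abs: float
    max_abs: float
    n: int

    def to_dict(self) -> dict:
        return {"mean_abs": self.mean_abs, "max_abs": self.max_abs, "n": self.n}


def quantize_24_to_16(samples24: np.ndarray) -> tuple[np.ndarray, ConversionErrorStats]:
    """Drop the least significant byte of signed 24-bit samples.

    Truncation is an arithmetic shift toward −∞ (floor division by 2⁸), so
    the per-sample error lies in [0, 255] codes, i.e. strictly below 2⁻¹⁶ of
    the full-scale range; samples whose low byte is zero convert losslessly.
    """
    s24 = np.asarray(samples24)
    if not np.issubdtype(s24.dtype, np.integer):
        raise TypeError("quantize_24_to_16 expects integer samples")
    if s24.size and (s24.min() < INT24_MIN or s24.max() > INT24_MAX):
        raise ValueError("samples exceed the signed 24-bit range")
    s64 = s24.astype(np.int64)
    s16 = np.right_shift(s64, 8).astype(np.int16)
    err = s64 - (s16.astype(np.int64) << 8)  # in [0, 255]
    if s24.size:
        stats = ConversionErrorStats(
            mean_abs=float(err.mean()) / FULL_SCALE_24,
            max_abs=float(err.max()) / FULL_SCALE_24,
            n=int(s24.size),
        )
    else:
        stats = ConversionErrorStats(0.0, 0.0, 0)
    return s16, stats


# ---------------------------------------------------------------------------
# 24-bit WAV I/O (stdlib wave; 3-byte little-endian signed PCM)


def write_wav24(path: str | Path, samples24: np.ndarray, fs: int) -> None:
    s = np.asarray(samples24)
    if not np.issubdtype(s.dtype, np.integer):
        raise TypeError("write_wav24 expects integer samples")
    if s.size and (s.min() < INT24_MIN or s.max() > INT24_MAX):
        raise ValueError("samples exceed the signed 24-bit range")
    v = (s.astype(np.int64) & 0xFFFFFF).astype(np.uint32)
    b = np.empty((s.size, 3), dtype=np.uint8)
    b[:, 0] = v & 0xFF
    b[:, 1] = (v >> 8) & 0xFF
    b[:, 2] = (v >> 16) & 0xFF
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(3)
        w.setframerate(int(fs))
        w.writeframes(b.tobytes())


def read_wav24(path: str | Path) -> tuple[np.ndarray, int]:
    with wave.open(str(path), "rb") as w:
        if w.getsampwidth() != 3:
            raise ValueError(f"{path}: expected 24-bit PCM, got {8 * w.getsampwidth()}-bit")
        if w.getnchannels() != 1:
            raise ValueError(f"{path}: expected mono audio")
        fs = w.getframerate()
        raw = np.frombuffer(w.readframes(w.getnframes()), dtype=np.uint8)
    b = raw.reshape(-1, 3).astype(np.int64)
    v = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
    v[v >= 2**23] -= 2**24  # sign extension
    return v.astype(np.int32), fs


def write_wav16(path: str | Path, samples16: np.ndarray, fs: int) -> None:
    s = np.asarray(samples16, dtype=np.int16)
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(int(fs))
        w.writeframes(s.tobytes())


def physical_to_int24(signal: Signal) -> np.ndarray:
    """Map a physical-unit audio signal onto the signed 24-bit code range."""
    span = signal.physical_max - signal.physical_min
    x = (np.asarray(signal.samples, dtype=np.float64) - signal.physical_min) / span
    codes = np.round(x * (FULL_SCALE_24 - 1)) + INT24_MIN
    return np.clip(codes, INT24_MIN, INT24_MAX).astype(np.int32)


# ---------------------------------------------------------------------------
# EDF writing / reading (16-bit, 1 s data records)

_RECORD_S = 1.0


def _fmt(value, width: int) -> bytes:
    s = f"{value}"
    if isinstance(value, float):
        s = f"{value:g}"
    if len(s) > width:
        raise EDFError(f"field {s!r} exceeds {width} ascii characters")
    return s.ljust(width).encode("ascii")


def _phys_to_dig(x: np.ndarray, spec_or_sig) -> np.ndarray:
    pmin, pmax = spec_or_sig.physical_min, spec_or_sig.physical_max
    dmin, dmax = spec_or_sig.digital_min, spec_or_sig.digital_max
    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.round((np.asarray(x, dtype=np.float64) - pmin) * scale) + dmin
    return np.clip(dig, dmin, dmax).astype(np.int16)


def _dig_to_phys(d: np.ndarray, pmin, pmax, dmin, dmax) -> np.ndarray:
    scale = (pmax - pmin) / (dmax - dmin)
    return (d.astype(np.float64) - dmin) * scale + pmin


def write_edf(
    study: Study,
    path: str | Path,
    table: dict[str, ChannelSpec] | None = None,
    channel_order: list[str] | None = None,
) -> None:
    """Write the study's channels to a 16-bit EDF with 1 s records.

    Channels are validated against the channel table (label, sampling rate,
    ranges); the final partial second, if any, is zero-padded.
    """
    table = table if table is not None else CHANNEL_TABLE
    if not study.channels:
        raise ValueError("study has no channels to write")
    keys = channel_order or [k for k in table if k in study.channels]
    extra = set(study.channels) - set(keys)
    if extra - set(table):
        raise KeyError(f"channels not in the channel table: {sorted(extra - set(table))}")
    for key in keys:
        if key not in table:
            raise KeyError(f"channel key {key!r} not in the channel table")
        sig = study.channels[key]
        if sig.fs != table[key].fs:
            raise ValueError(
                f"channel {key!r}: fs {sig.fs} does not match the table ({table[key].fs})"
            )

    n_records = int(np.ceil(study.duration_s / _RECORD_S))
    if n_records <= 0:
        raise ValueError("study has zero duration")
    sprs = [int(round(table[k].fs * _RECORD_S)) for k in keys]
    total_spr = sum(sprs)

    block = np.zeros((n_records, total_spr), dtype=np.int16)
    col = 0
    for key, spr in zip(keys, sprs):
        sig = study.channels[key]
        dig = _phys_to_dig(sig.samples, sig)
        pad_dig = _phys_to_dig(np.zeros(1), sig)[0]
        full = np.full(n_records * spr, pad_dig, dtype=np.int16)
        full[: len(dig)] = dig[: n_records * spr]
        block[:, col : col + spr] = full.reshape(n_records, spr)
        col += spr

    ns = len(keys)
    header_bytes = 256 + ns * 256
    patient = f"{study.patient_id} {study.gender} {study.age}"
    hdr = b"".join([
        _fmt("0", 8),
        _fmt(patient, 80),
        _fmt("somnoscore", 80),
        _fmt("01.01.00", 8),
        _fmt("00.00.00", 8),
        _fmt(header_bytes, 8),
        b" " * 44,
        _fmt(n_records, 8),
        _fmt(int(_RECORD_S), 8),
        _fmt(ns, 4),
    ])
    fields = []
    for key in keys:
        fields.append(_fmt(table[key].label, 16))
    for key in keys:
        fields.append(_fmt(table[key].transducer, 80))
    for key in keys:
        fields.append(_fmt("a.u.", 8))
    for key in keys:
        fields.append(_fmt(float(table[key].physical_min), 8))
    for key in keys:
        fields.append(_fmt(float(table[key].physical_max), 8))
    for key in keys:
        fields.append(_fmt(table[key].digital_min, 8))
    for key in keys:
        fields.append(_fmt(table[key].digital_max, 8))
    for key in keys:
        fields.append(b" " * 80)  # prefiltering
    for spr in sprs:
        fields.append(_fmt(spr, 8))
    for key in keys:
        fields.append(b" " * 32)

    with open(path, "wb") as f:
        f.write(hdr)
        f.writelines(fields)
        block.astype("<i2").tofile(f)


def _read_field(buf: bytes, off: int, width: int) -> str:
    if off + width > len(buf):
        raise EDFError(f"truncated header at byte {off}")
    return buf[off : off + width].decode("ascii", errors="replace").strip()


def read_edf(path: str | Path) -> Study:
    """Read an EDF into a channels-only :class:`Study`.

    Duplicate ``'Flow Patient'`` labels are disambiguated in file order
    (cannula first) exactly as the writer emits them.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise EDFError(f"truncated header at byte {len(raw)}")
    try:
        header_bytes = int(_read_field(raw, 184, 8))
        n_records = int(_read_field(raw, 236, 8))
        record_s = float(_read_field(raw, 244, 8))
        ns = int(_read_field(raw, 252, 4))
    except ValueError as exc:
        raise EDFError(f"malformed numeric header field near byte 184: {exc}") from None
    if header_bytes != 256 + ns * 256:
        raise EDFError(f"inconsistent header size field at byte 184 ({header_bytes})")
    if len(raw) < header_bytes:
        raise EDFError(f"truncated header at byte {len(raw)}")

    patient = _read_field(raw, 8, 80)
    pid, gender, age = 1, "M", 0
    parts = patient.split()
    if len(parts) >= 3 and parts[0].isdigit() and parts[1] in ("M", "F"):
        pid, gender = int(parts[0]), parts[1]
        if parts[2].lstrip("-").isdigit():
            age = int(parts[2])

    def sig_field(block: int, width: int, i: int) -> str:
        return _read_field(raw, 256 + block + width * i, width)

    off = 0
    labels = [sig_field(off, 16, i) for i in range(ns)]; off += 16 * ns
    transducers = [sig_field(off, 80, i) for i in range(ns)]; off += 80 * ns
    off += 8 * ns  # physical dimension
    pmins = [float(sig_field(off, 8, i)) for i in range(ns)]; off += 8 * ns
    pmaxs = [float(sig_field(off, 8, i)) for i in range(ns)]; off += 8 * ns
    dmins = [int(sig_field(off, 8, i)) for i in range(ns)]; off += 8 * ns
    dmaxs = [int(sig_field(off, 8, i)) for i in range(ns)]; off += 8 * ns
    off += 80 * ns  # prefiltering
    sprs = [int(sig_field(off, 8, i)) for i in range(ns)]

    total_spr = sum(sprs)
    expected = header_bytes + n_records * total_spr * 2
    if len(raw) < expected:
        raise EDFError(
            f"data truncated at byte {len(raw)} (expected {expected})"
        )
    data = np.frombuffer(raw, dtype="<i2", offset=header_bytes,
                         count=n_records * total_spr).reshape(n_records, total_spr)

    channels: dict[str, Signal] = {}
    col = 0
    for i in range(ns):
        dig = data[:, col : col + sprs[i]].reshape(-1)
        col += sprs[i]
        phys = _dig_to_phys(dig, pmins[i], pmaxs[i], dmins[i], dmaxs[i])
        fs = sprs[i] / record_s
        key = labels[i]
        suffix = 2
        while key in channels:
            key = f"{labels[i]} {suffix}"
            suffix += 1
        channels[key] = Signal(key, phys, fs, pmins[i], pmaxs[i], dmins[i], dmaxs[i])

    return Study(
        patient_id=pid, age=age, gender=gender, channels=channels,
        recording_time_h=n_records * record_s / 3600.0,
    )


# ---------------------------------------------------------------------------
# 1-hour cropping


def crop_hours(study: Study, part_s: float = 3600.0) -> list[Study]:
    """Split a study into 1 h parts (plus a shorter final remainder).

    Samples are partitioned; event and hypnogram timestamps stay global, and
    each event is assigned to the part containing its onset, so concatenating
    the parts' samples and pooling their events restores the original study.
    """
    total_s = study.duration_s
    if total_s <= 0:
        raise ValueError("study has zero duration")
    n_parts = int(np.ceil(total_s / part_s))
    parts: list[Study] = []
    for i in range(n_parts):
        t0, t1 = i * part_s, min((i + 1) * part_s, total_s)
        channels = {}
        for key, sig in study.channels.items():
            i0 = int(round(t0 * sig.fs))
            i1 = min(sig.n_samples, int(round(t1 * sig.fs)))
            channels[key] = Signal(sig.label, sig.samples[i0:i1], sig.fs,
                                   sig.physical_min, sig.physical_max,
                                   sig.digital_min, sig.digital_max)
        events = [e for e in study.events if t0 <= e.start_s < t1]
        hypnogram = [
            (idx, stage) for idx, stage in study.hypnogram
            if t0 <= idx * study.epoch_s < t1
        ]
        parts.append(Study(
            patient_id=study.patient_id, age=study.age, gender=study.gender,
            channels=channels, hypnogram=hypnogram, events=events,
            epoch_s=study.epoch_s, recording_time_h=(t1 - t0) / 3600.0,
        ))
    return parts


# ---------------------------------------------------------------------------
# RML annotation sidecar (minimal XML dialect)


def write_rml(
    study: Study,
    path: str | Path,
    clean: bool = False,
    accepted: list[EventAnnotation] | None = None,
    strict_durations: bool = True,
) -> Path:
    """Write annotations (patient, stages, events) to an RML-style XML file.

    With ``clean=True`` only validation-accepted events are written and the
    output filename gains the ``clean_`` prefix; returns the path written.
    """
    path = Path(path)
    events = list(study.events)
    if clean:
        if accepted is None:
            raise ValueError("clean=True requires the accepted event list")
        keep = set(id(e) for e in accepted)
        non_resp = [e for e in events if e.type not in RESPIRATORY_SCORED_TYPES]
        events = sorted(
            [e for e in events if id(e) in keep] + non_resp,
            key=lambda e: e.start_s,
        )
        path = path.with_name("clean_" + path.name)
    _check_durations(events, strict_durations)

    root = ET.Element("PatientStudy", {"schema_version": "1"})
    pat = ET.SubElement(root, "Patient")
    ET.SubElement(pat, "Id").text = str(study.patient_id)
    ET.SubElement(pat, "Age").text = str(study.age)
    ET.SubElement(pat, "Gender").text = study.gender
    stages = ET.SubElement(root, "SleepStages", {"EpochLength": repr(study.epoch_s)})
    for idx, stage in study.hypnogram:
        ET.SubElement(stages, "Stage", {"Type": stage, "Start": repr(idx * study.epoch_s)})
    evs = ET.SubElement(root, "Events")
    for e in events:
        ET.SubElement(evs, "Event", {
            "Family": e.family, "Type": e.type,
            "Start": repr(e.start_s), "Duration": repr(e.duration_s),
        })
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
    return path


def _check_durations(events: list[EventAnnotation], strict: bool) -> None:
    if not strict:
        return
    for e in events:
        if e.type in RESPIRATORY_SCORED_TYPES and e.duration_s < MIN_EVENT_DURATION_S:
            raise ValueError(
                f"{e.type} at {e.start_s:.1f}s lasts {e.duration_s:.1f}s, below the "
                f"{MIN_EVENT_DURATION_S:.0f}s scoring minimum"
            )


def read_rml(path: str | Path, strict_durations: bool = True) -> Study:
    """Read an RML sidecar into a channels-less :class:`Study`."""
    tree = ET.parse(str(path))
    root = tree.getroot()
    if root.tag != "PatientStudy":
        raise ValueError(f"{path}: not an RML annotation file (root {root.tag!r})")
    pat = root.find("Patient")
    pid = int(pat.findtext("Id", "1"))
    age = int(pat.findtext("Age", "0"))
    gender = pat.findtext("Gender", "M")
    stages_el = root.find("SleepStages")
    epoch_s = float(stages_el.get("EpochLength", "30")) if stages_el is not None else 30.0
    hypnogram = []
    if stages_el is not None:
        for st in stages_el.findall("Stage"):
            start = float(st.get("Start"))
            hypnogram.append((int(round(start / epoch_s)), st.get("Type")))
    events = []
    evs_el = root.find("Events")
    for i, el in enumerate([] if evs_el is None else list(evs_el)):
        try:
            events.append(EventAnnotation(
                family=el.get("Family"), type=el.get("Type"),
                start_s=float(el.get("Start")), duration_s=float(el.get("Duration")),
            ))
        except TaxonomyError as exc:
            raise TaxonomyError(
                f"event #{i} (start {el.get('Start')}s): {exc}"
            ) from None
    _check_durations(events, strict_durations)
    return Study(patient_id=pid, age=age, gender=gender, hypnogram=hypnogram,
                 events=events, epoch_s=epoch_s)


__all__ = [
    "ConversionErrorStats",
    "EDFError",
    "FULL_SCALE_24",
    "crop_hours",
    "physical_to_int24",
    "quantize_24_to_16",
    "read_edf",
    "read_rml",
    "read_wav24",
    "write_edf",
    "write_rml",
    "write_wav16",
    "write_wav24",
]
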