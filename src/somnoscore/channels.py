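"""The dataset's EDF channel dialect.

Every study carries the same channel set; per-label sampling frequency and
physical/digital ranges are fixed.  Two nasal airflow sensors share the EDF
label ``'Flow Patient'`` (a pressure cannula and a thermistor); in memory they
are disambiguated as ``'Flow Patient'`` (cannula) and ``'Flow Patient 2'``
(thermistor), and the EDF transducer field records which sensor is which.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ChannelSpec:
    label: str              # label as written in the EDF header
    transducer: str
    fs: float
    physical_min: float
    physical_max: float
    digital_min: int
    digital_max: int


#: In-memory key -> channel spec.  Keys are unique; ``label`` need not be.
CHANNEL_TABLE: dict[str, ChannelSpec] = {
    "EEG A1-A2": ChannelSpec("EEG A1-A2", "AgAgCl electrode", 200, -313, 313, -32768, 32767),
    "EEG C3-A2": ChannelSpec("EEG C3-A2", "AgAgCl electrode", 200, -313, 313, -32768, 32767),
    "EEG C4-A1": ChannelSpec("EEG C4-A1", "AgAgCl electrode", 200, -313, 313, -32768, 32767),
    "EOG LOC-A2": ChannelSpec("EOG LOC-A2", "AgAgCl electrode", 200, -313, 313, -32768, 32767),
    "EOG ROC-A2": ChannelSpec("EOG ROC-A2", "AgAgCl electrode", 200, -313, 313, -32768, 32767),
    "EMG Chin": ChannelSpec("EMG Chin", "AgAgCl electrode", 200, -78, 78, -32768, 32767),
    "Leg 1": ChannelSpec("Leg 1", "Piezo sensor", 200, -78, 78, -32768, 32767),
    "Leg 2": ChannelSpec("Leg 2", "Piezo sensor", 200, -78, 78, -32768, 32767),
    "ECG I": ChannelSpec("ECG I", "AgAgCl electrode", 200, -8333, 8333, -32768, 32767),
    "RR": ChannelSpec("RR", "Derived from ECG", 1, 0, 200, 0, 200),
    "Snore": ChannelSpec("Snore", "Tracheal contact microphone", 500, -100, 100, -32768, 32767),
    "Flow Patient": ChannelSpec("Flow Patient", "Pressure cannula", 100, -100, 100, -32768, 32767),
    "Flow Patient 2": ChannelSpec("Flow Patient", "Thermistor", 100, -100, 100, -32768, 32767),
    "Effort THO": ChannelSpec("Effort THO", "Thoracic belt", 100, -100, 100, -32768, 32767),
    "Effort ABD": ChannelSpec("Effort ABD", "Abdominal belt", 100, -100, 100, -32768, 32767),
    "SpO2": ChannelSpec("SpO2", "Pulse oximeter", 1, 0, 102.3, 0, 1023),
    "Body": ChannelSpec("Body", "Position sensor", 1, 0, 255, 0, 255),
    "PulseRate": ChannelSpec("PulseRate", "Derived from ECG", 1, 0, 255, 0, 255),
    "Tracheal": ChannelSpec("Tracheal", "HQ tracheal contact microphone", 48000, -100, 100, -32768, 32767),
    "Microphone": ChannelSpec("Microphone", "Ambient condenser microphone", 48000, -100, 100, -32768, 32767),
}

#: The two airflow sensors used by the screening stage (cannula, thermistor).
FLOW_KEYS = ("Flow Patient", "Flow Patient 2")

#: Channel set written by default, in EDF file order.
DEFAULT_CHANNEL_ORDER = tuple(CHANNEL_TABLE)


def spec_for(key: str) -> ChannelSpec:
    try:
        return CHANNEL_TABLE[key]
    except KeyError:
        raise KeyError(f"channel key {key!r} is not in the channel table") from None


__all__ = ["CHANNEL_TABLE", "ChannelSpec", "DEFAULT_CHANNEL_ORDER", "FLOW_KEYS", "spec_for"]
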