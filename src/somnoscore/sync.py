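"""Synchronization of separately recorded audio with the PSG clock.

The PSG system and the high-quality audio recorder are started independently,
so the audio carries an unknown constant start-time offset.  Both devices see
the same tracheal sound: the PSG through its built-in 500 Hz ``Snore``
contact-microphone channel, the recorder at 48 kHz.  The offset is estimated
by (1) resampling the high-quality audio to the common 500 Hz rate,
(2) extracting the Hilbert-transform envelope of both signals, and
(3) locating the lag that maximizes their normalized cross-correlation.
At least 10 minutes of signal are examined; an estimate whose correlation
peak is wider than 2 s (at 90 % of its height) is rejected, and the study is
excluded rather than aligned with an unreliable offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from .types import Signal, Study

#: Minimum examined overlap for an accepted estimate (s).
MIN_EXAMINED_S = 600.0
#: Maximum tolerated width of the correlation peak for acceptance (s).
MAX_UNCERTAINTY_S = 2.0
#: Fraction of the peak height at which the peak width is measured.
PEAK_WIDTH_FRACTION = 0.9
#: Minimum normalized peak correlation for acceptance; two unrelated
#: envelopes can show a narrow but meaningless argmax, this gate screens it.
MIN_PEAK_CORR = 0.5


class SyncRejectedError(RuntimeError):
    """Raised when an operation requires an accepted lag estimate."""


@dataclass(frozen=True)
class LagEstimate:
    """Result of the envelope cross-correlation.

    ``lag_s`` is positive when the audio recorder started after the PSG.
    """

    lag_s: float
    peak_corr: float
    examined_s: float
    accepted: bool
    uncertainty_s: float


def resample_to(signal: Signal, target_fs: float) -> Signal:
    """Polyphase anti-aliased resampling to ``target_fs``."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if signal.n_samples == 0:
        raise ValueError("cannot resample a zero-length signal")
    if target_fs == signal.fs:
        return signal
    frac = Fraction(target_fs / signal.fs).limit_denominator(10**6)
    up, down = frac.numerator, frac.denominator
    samples = sps.resample_poly(np.asarray(signal.samples, dtype=np.float64), up, down)
    return Signal(signal.label, samples, target_fs, signal.physical_min,
                  signal.physical_max, signal.digital_min, signal.digital_max)


def hilbert_envelope(signal: Signal, smooth_hz: float | None = 2.0) -> Signal:
    """Magnitude of the analytic signal, optionally low-pass smoothed.

    Breathing modulates tracheal sound below ~0.5 Hz, so a gentle 2 Hz
    low-pass on the raw Hilbert magnitude stabilizes the correlation peak
    without touching the modulation of interest.
    """
    x = np.asarray(signal.samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    n = x.size
    env = np.abs(sps.hilbert(x, N=next_fast_len(n))[:n])
    if smooth_hz is not None and smooth_hz < 0.5 * signal.fs:
        sos = sps.butter(4, smooth_hz, btype="low", fs=signal.fs, output="sos")
        env = sps.sosfiltfilt(sos, env)
        np.maximum(env, 0.0, out=env)
    return Signal(signal.label, env, signal.fs, signal.physical_min,
                  signal.physical_max, signal.digital_min, signal.digital_max)


def _normalized_xcorr(a: np.ndarray, b: np.ndarray, fs: float, max_lag_s: float):
    """Overlap-normalized cross-correlation restricted to |lag| <= max_lag_s.

    Returns (lags in samples, normalized correlation).  Both inputs are
    centred on their global means; each lag is normalized by the energy of
    the overlapping stretches only, so edge lags are not biased low.
    """
    a = a - a.mean()
    b = b - b.mean()
    if np.allclose(a, 0.0) or np.allclose(b, 0.0):
        raise ValueError("correlation undefined for an all-zero envelope")
    raw = sps.correlate(a, b, mode="full", method="fft")
    lags = sps.correlation_lags(len(a), len(b), mode="full")
    max_lag = int(round(max_lag_s * fs))
    keep = np.abs(lags) <= max_lag
    lags, raw = lags[keep], raw[keep]

    ca2 = np.concatenate([[0.0], np.cumsum(a * a)])
    cb2 = np.concatenate([[0.0], np.cumsum(b * b)])
    na, nb = len(a), len(b)
    # overlap for lag k: a[max(k,0) : min(na, nb+k)] vs the matching b stretch
    a_lo = np.maximum(lags, 0)
    a_hi = np.minimum(na, nb + lags)
    b_lo = a_lo - lags
    b_hi = a_hi - lags
    ea = ca2[a_hi] - ca2[a_lo]
    eb = cb2[b_hi] - cb2[b_lo]
    denom = np.sqrt(ea * eb)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > 0, raw / denom, 0.0)
    return lags, ncc, a_hi - a_lo


def estimate_lag(
    env_a: Signal,
    env_b: Signal,
    max_lag_s: float = 120.0,
    *,
    min_examined_s: float = MIN_EXAMINED_S,
    min_peak_corr: float = MIN_PEAK_CORR,
) -> LagEstimate:
    """Lag of ``env_b`` relative to ``env_a`` by normalized cross-correlation.

    Positive lag: ``env_b`` (the audio) starts after ``env_a`` (the PSG).
    """
    if env_a.fs != env_b.fs:
        raise ValueError("envelopes must share a sampling rate")
    fs = env_a.fs
    lags, ncc, overlaps = _normalized_xcorr(
        np.asarray(env_a.samples), np.asarray(env_b.samples), fs, max_lag_s
    )
    i = int(np.argmax(ncc))
    peak = float(ncc[i])
    lag_s = float(lags[i]) / fs
    examined_s = float(overlaps[i]) / fs

    # width of the contiguous region around the peak above 90 % of its height
    thresh = PEAK_WIDTH_FRACTION * peak
    lo = i
    while lo > 0 and ncc[lo - 1] >= thresh:
        lo -= 1
    hi = i
    while hi < len(ncc) - 1 and ncc[hi + 1] >= thresh:
        hi += 1
    uncertainty_s = float(hi - lo + 1) / fs

    accepted = (
        uncertainty_s <= MAX_UNCERTAINTY_S
        and examined_s >= min_examined_s
        and peak >= min_peak_corr
    )
    return LagEstimate(lag_s, peak, examined_s, accepted, uncertainty_s)


def align_audio(study: Study, audio: Signal, lag: LagEstimate) -> Study:
    """Insert separately recorded audio into the study on the PSG clock.

    The audio is shifted by ``-lag_s`` and zero-padded where no audio exists,
    then truncated to the PSG duration.  Requires an accepted estimate; a
    rejected one means the study should be excluded, as unsynchronizable
    recordings are dropped rather than force-aligned.
    """
    if not lag.accepted:
        raise SyncRejectedError(
            "lag estimate was rejected (peak too wide/low or overlap short); "
            "exclude this study instead of aligning it"
        )
    fs = audio.fs
    n_out = int(round(study.duration_s * fs))
    shift = int(round(lag.lag_s * fs))
    out = np.zeros(n_out, dtype=np.asarray(audio.samples).dtype)
    src = np.asarray(audio.samples)
    # audio sample j was recorded at PSG time (j + shift)/fs
    dst_lo = max(shift, 0)
    dst_hi = min(n_out, shift + len(src))
    if dst_hi > dst_lo:
        out[dst_lo:dst_hi] = src[dst_lo - shift : dst_hi - shift]
    aligned = Signal(audio.label, out, fs, audio.physical_min, audio.physical_max,
                     audio.digital_min, audio.digital_max)
    new_channels = dict(study.channels)
    new_channels[audio.label] = aligned
    return Study(
        patient_id=study.patient_id,
        age=study.age,
        gender=study.gender,
        channels=new_channels,
        hypnogram=list(study.hypnogram),
        events=list(study.events),
        epoch_s=study.epoch_s,
        recording_time_h=study.recording_time_h,
    )


__all__ = [
    "LagEstimate",
    "MAX_UNCERTAINTY_S",
    "MIN_EXAMINED_S",
    "MIN_PEAK_CORR",
    "SyncRejectedError",
    "align_audio",
    "estimate_lag",
    "hilbert_envelope",
    "resample_to",
]
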