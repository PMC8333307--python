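"""Study-level sleep-apnea indices and association statistics.

The apnea/hypopnea index (AHI) is the count of scored apnea + hypopnea
events per hour of total sleep time (TST); the apnea index (AI) counts only
apneas of any type, the hypopnea index (HI) only hypopneas, and the oxygen
desaturation index (ODI) counts relative SpO2 desaturations (≥3 % drops) per
sleep hour.  Severity follows the standard AHI cut points: Normal < 5,
Mild [5, 15), Moderate [15, 30), Severe ≥ 30 events/h.

Beyond the indices, this module measures what home-based screening systems
care about: the AHI computed over recording time instead of TST (the value a
device without sleep staging would report), the intra-night stability of the
cumulative AHI, the association of desaturations (onset within 60 s of the
event onset) and arousals (onset within 5 s of the event end) with
respiratory events, and per-type event duration summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    APNEA_TYPES,
    DEFAULT_EPOCH_S,
    EventAnnotation,
    RESPIRATORY_SCORED_TYPES,
    SLEEP_STAGES,
    sort_events,
)

SEVERITY_CLASSES = ("Normal", "Mild", "Moderate", "Severe")
#: AHI (events/h) lower bounds of Mild / Moderate / Severe.
SEVERITY_THRESHOLDS = (5.0, 15.0, 30.0)

DESAT_WINDOW_S = 60.0
AROUSAL_WINDOW_S = 5.0


def classify_severity(ahi: float) -> str:
    """Severity class from AHI; the boundary values 5/15/30 round up."""
    if ahi < 0:
        raise ValueError("AHI cannot be negative")
    if ahi < SEVERITY_THRESHOLDS[0]:
        return "Normal"
    if ahi < SEVERITY_THRESHOLDS[1]:
        return "Mild"
    if ahi < SEVERITY_THRESHOLDS[2]:
        return "Moderate"
    return "Severe"


def total_sleep_time(
    hypnogram: list[tuple[int, str]], epoch_s: float = DEFAULT_EPOCH_S
) -> float:
    """TST in hours: count of non-Wake epochs times the epoch length."""
    if not hypnogram:
        raise ValueError("empty hypnogram")
    n_sleep = 0
    for _, stage in hypnogram:
        if stage not in SLEEP_STAGES:
            raise ValueError(f"unknown sleep stage {stage!r}")
        if stage != "W":
            n_sleep += 1
    return n_sleep * epoch_s / 3600.0


@dataclass(frozen=True)
class ScoreSummary:
    tst_h: float
    recording_h: float
    ahi: float
    ai: float
    hi: float
    odi: float
    ahi_recording: float
    severity: str
    severity_recording: str

    def to_dict(self) -> dict:
        return {
            "tst_h": self.tst_h, "recording_h": self.recording_h,
            "ahi": self.ahi, "ai": self.ai, "hi": self.hi, "odi": self.odi,
            "ahi_recording": self.ahi_recording,
            "severity": self.severity,
            "severity_recording": self.severity_recording,
        }


def compute_indices(
    events: list[EventAnnotation],
    desats: list[EventAnnotation],
    tst_h: float,
    recording_h: float | None = None,
) -> ScoreSummary:
    """AHI/AI/HI/ODI and severity for one study."""
    if tst_h <= 0:
        raise ValueError("tst_h must be positive")
    recording_h = recording_h if recording_h is not None else tst_h
    n_apnea = sum(1 for e in events if e.type in APNEA_TYPES)
    n_hyp = sum(1 for e in events if e.type == "Hypopnea")
    n_resp = n_apnea + n_hyp
    ahi = n_resp / tst_h
    ahi_rec = n_resp / recording_h if recording_h > 0 else 0.0
    odi = sum(1 for d in desats if d.type == "RelativeDesaturation") / tst_h
    return ScoreSummary(
        tst_h=tst_h, recording_h=recording_h,
        ahi=ahi, ai=n_apnea / tst_h, hi=n_hyp / tst_h, odi=odi,
        ahi_recording=ahi_rec,
        severity=classify_severity(ahi),
        severity_recording=classify_severity(ahi_rec),
    )


# ---------------------------------------------------------------------------
# Intra-night AHI variability


@dataclass(frozen=True)
class AhiCurve:
    """Cumulative AHI over elapsed sleep time, against the final value."""

    times_h: np.ndarray          # grid of elapsed sleep hours
    cumulative_ahi: np.ndarray
    final_ahi: float
    relative_diff: np.ndarray    # (cumulative − final) / final at each time
    truncated: bool = False      # grid clipped because it ran beyond the TST


def _sleep_elapsed_at(
    t_s: np.ndarray, hypnogram: list[tuple[int, str]], epoch_s: float
) -> np.ndarray:
    """Elapsed sleep seconds at wall-clock times ``t_s``."""
    idx = sorted(hypnogram)
    sleep = np.array([stage != "W" for _, stage in idx], dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(sleep) * epoch_s])
    starts = np.array([i * epoch_s for i, _ in idx] + [ (idx[-1][0] + 1) * epoch_s ])
    out = np.empty_like(t_s, dtype=float)
    pos = np.searchsorted(starts, t_s, side="right") - 1
    pos = np.clip(pos, 0, len(idx) - 1)
    frac = np.clip((t_s - starts[pos]) / epoch_s, 0.0, 1.0)
    out = cum[pos] + frac * sleep[pos] * epoch_s
    out[t_s >= starts[-1]] = cum[-1]
    return out


def intra_night_ahi(
    events: list[EventAnnotation],
    hypnogram: list[tuple[int, str]],
    grid_h: np.ndarray | None = None,
    epoch_s: float = DEFAULT_EPOCH_S,
) -> AhiCurve:
    """Cumulative AHI on a grid of elapsed *sleep* hours.

    The denominator is elapsed sleep (non-Wake) time, consistent with the
    AHI definition; the last grid point is pinned to the full TST so the
    curve ends exactly at the final AHI.
    """
    tst_h = total_sleep_time(hypnogram, epoch_s)
    if tst_h <= 0:
        raise ValueError("TST must be positive")
    truncated = False
    if grid_h is None:
        grid = np.arange(1.0, np.floor(tst_h) + 1.0)
    else:
        grid = np.asarray(grid_h, dtype=float)
        if grid.size and grid.max() > tst_h + 1e-9:
            grid = grid[grid <= tst_h + 1e-9]
            truncated = True
    if grid.size == 0 or abs(grid[-1] - tst_h) > 1e-9:
        grid = np.append(grid, tst_h)

    resp = [e for e in events if e.type in RESPIRATORY_SCORED_TYPES]
    onsets = np.array([e.start_s for e in resp], dtype=float)
    sleep_at_onset_h = (
        _sleep_elapsed_at(onsets, hypnogram, epoch_s) / 3600.0
        if resp else np.empty(0)
    )
    counts = np.array([(sleep_at_onset_h <= t + 1e-12).sum() for t in grid], dtype=float)
    cumulative = counts / grid
    final = len(resp) / tst_h
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(final > 0, (cumulative - final) / final, 0.0)
    return AhiCurve(grid, cumulative, final, rel, truncated)


def cohort_ahi_variability(curves: list[AhiCurve], grid_h: np.ndarray) -> np.ndarray:
    """Mean |relative difference to final AHI| across studies at each time."""
    grid_h = np.asarray(grid_h, dtype=float)
    out = np.full(grid_h.shape, np.nan)
    for j, t in enumerate(grid_h):
        vals = [
            np.interp(t, c.times_h, c.relative_diff)
            for c in curves if c.times_h[-1] >= t
        ]
        if vals:
            out[j] = float(np.mean(np.abs(vals)))
    return out


# ---------------------------------------------------------------------------
# Desaturation / arousal association


@dataclass
class AssociationResult:
    pairs: list[tuple[EventAnnotation, EventAnnotation, float]] = field(default_factory=list)
    n_events: int = 0
    fraction_overall: float = 0.0
    fraction_by_type: dict[str, float] = field(default_factory=dict)
    mean_delay_s: float = float("nan")
    fraction_delay_ge_10s: float = float("nan")

    @property
    def delays_s(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs])

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_associated": len(self.pairs),
            "fraction_overall": self.fraction_overall,
            "fraction_by_type": self.fraction_by_type,
            "mean_delay_s": self.mean_delay_s,
            "fraction_delay_ge_10s": self.fraction_delay_ge_10s,
        }


def _associate(
    resp_events: list[EventAnnotation],
    companions: list[EventAnnotation],
    anchor: str,
    window_s: float,
) -> AssociationResult:
    """Greedy one-to-one pairing: each companion to the nearest-anchored event."""
    resp = sort_events(resp_events)
    comps = sort_events(companions)
    anchors = np.array(
        [e.start_s if anchor == "onset" else e.end_s for e in resp]
    )
    taken = np.zeros(len(resp), dtype=bool)
    pairs: list[tuple[EventAnnotation, EventAnnotation, float]] = []
    for c in comps:
        delays = c.start_s - anchors
        ok = (delays >= 0) & (delays <= window_s) & ~taken
        if not ok.any():
            continue
        idx = np.where(ok)[0]
        i = idx[np.argmin(delays[idx])]
        taken[i] = True
        pairs.append((resp[i], c, float(delays[i])))

    res = AssociationResult(pairs=pairs, n_events=len(resp))
    if resp:
        res.fraction_overall = len(pairs) / len(resp)
    by_type_n = {t: 0 for t in {e.type for e in resp}}
    by_type_k = dict.fromkeys(by_type_n, 0)
    for e in resp:
        by_type_n[e.type] += 1
    for e, _, _ in pairs:
        by_type_k[e.type] += 1
    res.fraction_by_type = {
        t: (by_type_k[t] / by_type_n[t] if by_type_n[t] else 0.0) for t in by_type_n
    }
    if pairs:
        d = res.delays_s
        res.mean_delay_s = float(d.mean())
        res.fraction_delay_ge_10s = float((d >= 10.0).mean())
    return res


def associate_desaturations(
    resp_events: list[EventAnnotation],
    desat_events: list[EventAnnotation],
    window_s: float = DESAT_WINDOW_S,
) -> AssociationResult:
    """Pair desaturations whose onset lies within 60 s of an event onset."""
    return _associate(resp_events, desat_events, "onset", window_s)


def associate_arousals(
    resp_events: list[EventAnnotation],
    arousal_events: list[EventAnnotation],
    window_s: float = AROUSAL_WINDOW_S,
) -> AssociationResult:
    """Pair arousals whose onset lies within 5 s after an event's end."""
    return _associate(resp_events, arousal_events, "end", window_s)


# ---------------------------------------------------------------------------
# Duration statistics


def duration_stats(
    events: list[EventAnnotation], bins: int = 12
) -> dict[str, dict]:
    """Per-type duration summaries (mean/min/max/count + histogram)."""
    out: dict[str, dict] = {}
    for etype in RESPIRATORY_SCORED_TYPES:
        durs = np.array([e.duration_s for e in events if e.type == etype])
        if durs.size == 0:
            out[etype] = {"n": 0, "empty": True}
            continue
        hist, edges = np.histogram(durs, bins=bins)
        out[etype] = {
            "n": int(durs.size),
            "empty": False,
            "mean": float(durs.mean()),
            "min": float(durs.min()),
            "max": float(durs.max()),
            "histogram": hist.tolist(),
            "bin_edges": edges.tolist(),
        }
    return out


def score_study(
    events: list[EventAnnotation],
    hypnogram: list[tuple[int, str]],
    recording_h: float,
    epoch_s: float = DEFAULT_EPOCH_S,
) -> ScoreSummary:
    """Convenience wrapper: TST + indices from a study's annotations."""
    tst_h = total_sleep_time(hypnogram, epoch_s)
    resp = [e for e in events if e.type in RESPIRATORY_SCORED_TYPES]
    desats = [e for e in events if e.type == "RelativeDesaturation"]
    return compute_indices(resp, desats, tst_h, recording_h)


__all__ = [
    "AROUSAL_WINDOW_S",
    "AhiCurve",
    "AssociationResult",
    "DESAT_WINDOW_S",
    "SEVERITY_CLASSES",
    "SEVERITY_THRESHOLDS",
    "ScoreSummary",
    "associate_arousals",
    "associate_desaturations",
    "classify_severity",
    "cohort_ahi_variability",
    "compute_indices",
    "duration_stats",
    "intra_night_ahi",
    "score_study",
    "total_sleep_time",
]
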