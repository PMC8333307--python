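import numpy as np
import pytest

from somnoscore.synthetic import (
    PlannedEvent,
    SimulationConfig,
    generate_study,
    random_event_plan,
)


@pytest.fixture(scope="session")
def fixture_study():
    """Deterministic 10-min study used for the I/O round-trip tests.

    Carries the full PSG channel set except the 48 kHz audio channels (the
    Snore channel stands in for audio); six random events plus the known
    trio of planned reductions.
    """
    rng = np.random.default_rng(42)
    plan = random_event_plan(6, 600 / 3600, rng, margin_s=60.0)
    cfg = SimulationConfig(
        duration_h=600 / 3600,
        seed=42,
        event_plan=plan,
        audio_channels=("Snore",),
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def sync_pair_study():
    """640 s study with Snore + Tracheal channels for synchronization tests."""
    rng = np.random.default_rng(0)
    plan = random_event_plan(8, 640 / 3600, rng, margin_s=60.0)
    cfg = SimulationConfig(
        duration_h=640 / 3600,
        seed=0,
        event_plan=plan,
        audio_channels=("Snore", "Tracheal"),
        aux_channels=(),
    )
    return generate_study(cfg)


def planted_truth_study(seed: int, n_true: int = 30, n_false: int = 30):
    """Study mixing clearly apneic events with sub-threshold false positives.

    True events: ≥50 % flow reduction on both sensors, oscillation ceases.
    False positives: ≤20 % reduction with residual normal-rate breathing.
    Returns (study, truth flags aligned with the respiratory event list).
    """
    rng = np.random.default_rng(seed)
    events, truth = [], []
    t = 60.0
    for i in range(n_true + n_false):
        is_true = i % 2 == 0 if n_true == n_false else i < n_true
        if is_true:
            red = rng.uniform(0.5, 0.95)
            ev = PlannedEvent(
                "ObstructiveApnea", t, rng.uniform(12, 25),
                red, float(np.clip(red + rng.uniform(-0.05, 0.05), 0, 1)), False,
                with_desat=False, with_arousal=False,
            )
        else:
            red = rng.uniform(0.05, 0.2)
            ev = PlannedEvent(
                "Hypopnea", t, rng.uniform(12, 25),
                red, float(np.clip(red + rng.uniform(-0.05, 0.05), 0, 1)), True,
                with_desat=False, with_arousal=False,
            )
        events.append(ev)
        truth.append(is_true)
        t += ev.duration_s + 30.0 + rng.uniform(0, 20)
    cfg = SimulationConfig(
        duration_h=(t + 60.0) / 3600.0,
        seed=seed,
        breathing_rate_hz=0.25,
        event_plan=events,
        audio_channels=(),
        aux_channels=(),
    )
    return generate_study(cfg), truth
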