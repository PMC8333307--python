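# somnoscore

A toolkit for sleep-apnea polysomnography (PSG) studies that carry
separately recorded breathing audio. It covers the computational layer a
sleep lab or a home-screening researcher needs around scored overnight
recordings:

* **Synchronization** of high-quality 48 kHz tracheal/ambient audio with the
  PSG clock, via Hilbert-envelope cross-correlation against the PSG's
  built-in 500 Hz tracheal (Snore) channel;
* **Storage** in 16-bit EDF with a fixed clinical channel dialect, RML-style
  XML annotation sidecars, 24-bit WAV input with 24→16-bit conversion by
  least-significant-byte truncation, and 1-hour cropping;
* **Screening** of manually scored apnea/hypopnea events against the two
  nasal airflow sensors (pressure cannula + thermistor): an event must show
  a ≥ 30 % flow-envelope reduction on both usable sensors, with an optional
  breathing-rate (0.16–0.4 Hz) confirmation rule, producing "clean"
  annotation sets;
* **Scoring statistics**: AHI/AI/HI/ODI, severity class, total sleep time,
  desaturation association (60 s window from event onset), arousal
  association (5 s after event end), intra-night AHI variability and
  per-type duration summaries;
* A **synthetic PSG generator** with known ground truth (quasi-periodic
  breathing bursts, amplitude-reduction events of the four types, lagged
  SpO2 desaturations, arousals, a two-device recording pair with an
  injectable start-time offset) so every stage is testable without
  clinical data.

## The statistics in brief

For a study with total sleep time $TST$ (hours of non-Wake 30 s epochs),
$N_A$ scored apneas (obstructive + central + mixed), $N_H$ hypopneas and
$N_D$ relative (≥ 3 %) oxygen desaturations:

$$\mathrm{AHI} = \frac{N_A + N_H}{TST},\qquad
  \mathrm{AI} = \frac{N_A}{TST},\qquad
  \mathrm{HI} = \frac{N_H}{TST},\qquad
  \mathrm{ODI} = \frac{N_D}{TST}$$

with severity Normal (AHI < 5), Mild [5, 15), Moderate [15, 30),
Severe (≥ 30 events/h). The device offset between the PSG and the audio
recorder is $\hat\tau = \arg\max_\tau \rho\big(e_\mathrm{snore}(t),\,
e_\mathrm{audio}(t-\tau)\big)$ where $e$ are smoothed Hilbert envelopes at
the common 500 Hz rate and $\rho$ is the overlap-normalized
cross-correlation; estimates with a correlation peak wider than 2 s (at
90 % height) or under 10 min of examined overlap are rejected.
See `docs/methods.md` for the full model and parameter documentation.

## Worked example

Generate a 30-minute synthetic study with 25 planted events and score it:

```bash
somnoscore simulate --minutes 30 --seed 7 --events 25 --no-audio --out demo
somnoscore score --rml demo/study.rml --edf demo/study.edf
```

prints (abridged):

```json
{
  "summary": {
    "tst_h": 0.43333333333333335,
    "recording_h": 0.5,
    "ahi": 46.15384615384615,
    "ai": 30.0,
    "hi": 16.153846153846153,
    "odi": 36.92307692307692,
    "ahi_recording": 40.0,
    "severity": "Severe",
    "severity_recording": "Severe"
  },
  "desaturation_association": {
    "n_events": 20,
    "n_associated": 16,
    "fraction_overall": 0.8,
    "mean_delay_s": 25.0
  },
  "arousal_association": {
    "n_events": 20,
    "n_associated": 15,
    "fraction_overall": 0.75,
    "mean_delay_s": 2.5
  }
}
```

Reading: the generator placed 20 respiratory events (the 30-min window fits
20 of the 25 requested) over 26 min of sleep, giving AHI = 20/0.433 ≈ 46
events/h — Severe; the apnea-only rate is AI = 30/h and the hypopnea rate
HI ≈ 16.2/h. Dividing by recording time instead of sleep time (what a
home device without sleep staging would measure) lowers the index to 40.
16 of 20 events were followed by a ≥ 3 % desaturation within the 60 s
window (the generator draws desaturations with probability 0.7, lagged
25 s — hence the mean delay), and 15 of 20 by an arousal within 5 s of the
event end.

Screening the same study's annotations against its flow channels:

```bash
somnoscore validate --edf demo/study.edf --rml demo/study.rml --out clean.rml
```

reports `"n_rejected": 0` — every planted event has a ≥ 50 % dual-sensor
reduction, so the 30 % rule keeps all of them and `ahi_after == ahi_before`.
Sub-threshold events (≤ 20 % reduction with ongoing normal-rate breathing)
are rejected with reason `insufficient-reduction`; see
`tests/test_validation.py` for planted-truth examples.

The other subcommands: `somnoscore sync` estimates and applies the
audio/PSG offset from an EDF + 24-bit WAV pair, and `somnoscore convert`
performs the 24→16-bit audio conversion, reporting the truncation-error
statistics (mean ≈ 7.6×10⁻⁶, max < 1.53×10⁻⁵ of full scale on dithered
audio).

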