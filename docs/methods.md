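# Methods

This note documents the models, parameters and numerical choices behind
`somnoscore`, and what the synthetic test-bed does and does not demonstrate
about real polysomnography (PSG) data.

## The problem

A sleep-apnea PSG study pairs a multichannel overnight recording (EEG/EOG/EMG,
ECG, two nasal airflow sensors, effort belts, SpO2, body position, a built-in
500 Hz tracheal contact microphone) with separately recorded high-quality
audio (48 kHz tracheal and ambient microphones, 24-bit WAV). Because the two
recorders are started independently, the audio carries an unknown constant
start-time offset relative to the PSG clock. Scored studies carry an event
list (obstructive/central/mixed apneas, hypopneas, desaturations, arousals,
…) and a hypnogram (sleep stage per 30 s epoch). `somnoscore` implements the
computational layer around such studies: synchronization, storage (EDF + RML
+ WAV), automatic screening of scored respiratory events against the flow
channels, and the scoring statistics (AHI/ODI, severity, associations,
intra-night variability).

## Synchronization

Both devices observe the same tracheal sound. The high-quality audio is
polyphase-resampled to the common 500 Hz rate, the Hilbert-transform envelope
of both signals is extracted, and the device offset is the lag maximizing
their normalized cross-correlation:

* **Envelope smoothing** — a 4th-order, 2 Hz low-pass (zero-phase) on the
  Hilbert magnitude. Breathing modulates tracheal sound below ~0.5 Hz, so
  this suppresses carrier ripple without touching the modulation.
  Configurable; raw envelopes are supported.
* **Normalization** — both envelopes are centred on their global means and
  each lag is normalized by the energy of the overlapping stretches only
  (Pearson-style), so edge lags are not biased.
* **Acceptance rule** — an estimate is accepted when (a) the examined
  overlap is ≥ 600 s, (b) the width of the correlation peak at 90 % of its
  height is ≤ 2 s, and (c) the peak correlation is ≥ 0.5. The peak width is
  a proxy for the synchronization error used to reject unsynchronizable
  studies; the peak-correlation gate exists because two unrelated envelopes
  can produce a narrow but meaningless argmax. Rejected studies raise an
  error on alignment rather than being force-aligned.
* **Alignment** — accepted audio is shifted onto the PSG clock, zero-padded
  where no audio exists, and truncated to the PSG duration.
* `max_lag_s` defaults to 120 s (operators start the recorders within tens
  of seconds of each other).

Only a constant offset is modeled; clock drift between devices is out of
scope.

## Storage

* **EDF** — plain 16-bit EDF with 1 s data records and the fixed channel
  table (labels, rates, physical/digital ranges). The two airflow sensors
  share the EDF label `Flow Patient`; the transducer field distinguishes
  the pressure cannula from the thermistor, and in-memory keys use
  `Flow Patient` / `Flow Patient 2` in file order. The final partial second
  is zero-padded. Round trips are bit-exact at 16-bit precision, and the
  writer's output is cross-checked against an independent EDF reader (mne)
  in the test suite. BDF (24-bit) is deliberately not produced.
* **24→16-bit conversion** — the least significant byte of each 24-bit
  sample is dropped (arithmetic shift toward −∞, i.e. floor division by
  2⁸). The per-sample error is 0–255 codes; as a fraction of the 2²⁴
  full-scale range it is bounded by 255/2²⁴ ≈ 1.5199×10⁻⁵ < 2⁻¹⁶, and its
  mean under a uniform code distribution is 127.5/2²⁴ ≈ 7.5996×10⁻⁶.
  Real audio material gives empirical means a fraction of a percent above
  the uniform value; the toolkit always reports the empirical statistic.
* **Cropping** — recordings are split into 1 h parts. Event and hypnogram
  timestamps stay global (seconds from recording start, half-open
  intervals), so the 60 s / 5 s association windows remain well-defined
  across part boundaries and crop-then-concatenate is the identity.
* **RML** — a minimal XML dialect (`PatientStudy` → `Patient{Id,Age,Gender}`,
  `SleepStages` → `Stage{Type,Start}`, `Events` →
  `Event{Family,Type,Start,Duration}`) carrying exactly the fields the
  toolkit consumes; the proprietary scoring-software schema is not
  reverse-engineered. The family→type taxonomy is enforced on both read and
  write; respiratory apnea/hypopnea events shorter than the 10 s scoring
  minimum are rejected unless strictness is lowered.

## Screening of scored respiratory events

Manual scorers err toward positives near the threshold, so scored event
lists contain false positives. Screening re-examines each scored
apnea/hypopnea against both airflow sensors:

1. **Envelope** — Hilbert magnitude, low-passed at 1 Hz (configurable),
   then morphological closing followed by opening with a 3 s structuring
   window. The closing fills the gaps between breath bursts and any dip
   shorter than 3 s (a single missed breath is not an event); the opening
   removes equally short bumps. Without the 1 Hz pre-smoothing, broadband
   noise peaks survive the max-filter and bias measured reductions low by
   ~0.06–0.09; with it, planted reductions are recovered within ±0.02 at
   5 % noise.
2. **Baseline** — the envelope maximum over the union of the 5 s frames
   immediately before and after the event (maximum over the union is the
   most conservative choice against false rejection). A flag optionally
   excludes frame samples overlapping neighbouring scored events.
3. **Reduction** — `1 − min(in-event envelope)/baseline`, clipped to [0,1].
4. **Sensor usability** — a sensor is excluded from the investigation for
   an event when its baseline falls below
   `max(0.05 × median(channel envelope), 0.05 × physical half-range)`.
   The relative term catches temporarily dislocated sensors; the absolute
   term (fraction of the ±100 a.u. physical range) is needed because a
   sensor that is flat noise for the whole night has a median at noise
   level, which a purely self-relative rule cannot flag.
5. **Decision** — the amplitude criterion requires ≥ 30 % reduction on
   every usable sensor (a reduction seen by only one sensor marks a false
   positive; `require_both_sensors=False` relaxes this to all-sensors-fail).
   When the breathing-rate rule is enabled (default), rejection additionally
   requires some usable sensor's in-event flow to keep a dominant frequency
   inside 0.16–0.4 Hz (a normal breath every 3–5 s): the rule acts as a
   confirmatory guard so that disturbed-but-reduced breathing is not
   rejected on amplitude alone. Events with no usable sensor are accepted
   and flagged *indeterminate* — never silently dropped.
6. **Dominant frequency** — detrended periodogram with a Hann window,
   zero-padded ×4 for peak interpolation, searched over (0, 1] Hz.
   Resolution is limited by event duration (~0.05 Hz at 20 s); for events
   near the 10 s minimum the estimate is coarse, which is acceptable for a
   guard that only needs in-band/out-of-band discrimination. An all-zero
   segment has no defined peak and the rule then cannot fire.

Accepted events can be re-emitted as a `clean_`-prefixed RML; screening
only removes events, so the post-screening AHI never exceeds the original.

## Scoring statistics

* AHI = scored apneas + hypopneas per hour of total sleep time (TST = count
  of non-Wake 30 s epochs); AI counts apneas of any type, HI hypopneas,
  ODI relative (≥3 %) desaturations per sleep hour. Only
  `RelativeDesaturation` events enter ODI; the absolute variant is read but
  not counted.
* Severity: Normal < 5, Mild [5, 15), Moderate [15, 30), Severe ≥ 30
  events/h; the boundary values belong to the higher class.
* `ahi_recording` divides by recording time instead of TST — the value a
  home device without sleep staging would report.
* Intra-night variability: the cumulative AHI on a grid of elapsed *sleep*
  hours (consistent with the AHI denominator), against the final AHI; a
  cohort helper averages |relative difference| across studies.
* Associations: a desaturation is associated with a respiratory event when
  its onset lies in [event onset, onset + 60 s]; an arousal when its onset
  lies in [event end, end + 5 s]. The 60 s window is one-sided after the
  onset (physiological lag); a symmetric option is configurable. Pairing is
  one-to-one by nearest onset when several events compete; delays before
  the window start are not associated (scorer jitter in event ends is not
  modeled). Reported: per-type and overall associated fractions, mean
  delay, and the fraction of desaturation delays ≥ 10 s.

## Synthetic study generator

The generator produces studies with known ground truth so every stage is
testable without clinical data:

* **Breathing flow** — raised-cosine inhale/exhale bursts at the configured
  breathing rate (default 0.25 Hz, constrained to 0.16–0.4 Hz), amplitude
  50 a.u. inside the ±100 a.u. physical range, plus white noise at
  `noise_level` (default 5 %) of the breathing amplitude. Bursts rather
  than a pure sinusoid give the envelope realistic short-time structure and
  actually exercise the 3 s suppression rule.
* **Events** — each planned event multiplies the per-sensor envelope by
  `1 − reduction` for its duration. With `residual_breathing` the oscillation
  persists at the reduced amplitude (sub-threshold false positives, mild
  hypopneas); without it the oscillation is replaced by a slow 0.07 Hz
  wander of the same reduced amplitude, keeping the event's amplitude scale
  while moving its dominant frequency below the breathing band. Planned
  reductions are recoverable from the screened envelope within ±0.05 on the
  residual-breathing surface; for full cessations the envelope reflects the
  wander's minima and therefore bounds the planned reduction from below
  only — harmless for screening, where cessations sit far above the 30 %
  threshold.
* **SpO2** — 96 % baseline with smooth dips of default depth 4 % starting
  25 s after flagged events (inside the 60 s association frame), clipped to
  [70, 100] %. Arousal annotations start 2.5 s after flagged event ends.
  Per-event desaturation/arousal flags default to Bernoulli draws with the
  configured probabilities.
* **Audio** — band-limited noise amplitude-modulated by the breathing
  profile (350 Hz–8 kHz for the 48 kHz tracheal channel, mirroring a
  contact microphone's passband; 20–200 Hz for the 500 Hz Snore channel),
  silenced inside events in proportion to the reduction. The two-device
  pair shares the modulation but not the carrier noise, so envelopes
  correlate while waveforms do not.
* **Random plans** — per-type durations are exponential above the 10 s
  minimum with means 19.07 / 16.10 / 24.65 / 16.16 s (obstructive /
  central / mixed / hypopnea), capped at 128.5 s; the obstructive type
  dominates the type mix, as in clinical cohorts.
* Other channels (EEG, EOG, EMG, ECG, effort, …) are noise placeholders at
  the correct rates and ranges — sufficient for I/O tests, not for any
  neurological analysis. The hypnogram is a deterministic wake-then-cycling
  pattern unless a plan is supplied.

What passing tests show: the synchronizer, screener and scorers recover the
generator's planted truth under realistic rates, event geometry and 5 %
noise. What they do not show: performance on real flow morphology (sensor
non-linearities, mouth breathing, movement artefacts), real audio content
(snoring spectra, ambient noise), or real hypnogram structure. Cohort-level
percentages from any particular clinical dataset are data-dependent and are
not reproduced here; the report layer reproduces the computations.

## Problem sizes and determinism

All randomness flows from a single integer seed per study
(`numpy.random.default_rng`); identical configurations are bit-identical.
The test-bed uses 10-minute studies for I/O and synchronization (640 s for
the two-device pair, keeping the post-offset overlap above the 10 min
examination minimum) and ~1-hour studies with 60 planted events for
screening; `scripts/acceptance.py` measures the synchronizer's worst
lag-recovery error over 10 independent 640 s realizations with a 20 s
injected offset. These sizes were chosen so the full loop stays
desk-scale while every window rule (3 s, 5 s, 60 s, 10 min) is exercised
at its native scale.
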