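# Methods

This note records the models, numerical choices and open design decisions
behind `neosleep`, and what the synthetic-data tests do and do not establish
about real recordings.

## Signal model and pipeline

The pipeline assumes a single-channel ECG sampled at 250 Hz (the bedside
standard), optional multichannel EEG at the same rate, and behavioral
annotations on non-overlapping 30-s epochs with labels AS (active sleep),
QS (quiet sleep) or AWAKE.

### Beat detection

Cardiac cycles are found from the analytic phase of the band-passed ECG.
Choices, all configurable through `detect_beats` arguments:

- **Band 5–30 Hz**, 2nd-order Butterworth applied forward–backward
  (zero phase). The band emphasizes the QRS complex and removes baseline
  wander; a narrow-band cycle then corresponds to one 2π rotation of the
  analytic phase, so beats are marked at upward zero crossings of the phase.
- **Refinement** to the local maximum of the filtered signal within ±50 ms,
  so the marked time sits on the R-wave peak rather than the phase crossing.
- **Amplitude gate**: candidates whose peak height falls below 25% of the
  median candidate height are discarded. The analytic phase keeps rotating
  through signal-free stretches; without the gate those rotations appear as
  spurious beats.
- **Physiological bounds** 0.2–2.0 s between beats (neonatal HR envelope
  50–250 bpm; the lower bound at 300 bpm leaves headroom for tachycardia).
  Detections closer than 0.2 s are treated as double detections and the
  smaller peak is dropped. Gaps longer than 2 s are left as gaps; the
  windowing stage handles them via beat counts.

Traces shorter than 2 s are rejected, as are zero-variance traces
("flatline").

### Beat-to-beat HR and correction

`hr[i] = 60 / (t[i+1] − t[i])`, timestamped at the later beat. Erroneous
beats are flagged against a **centered running median of 100 beats**
(~40 s at neonatal rates): deviations strictly greater than ±10 bpm are
replaced by the median value. Details that matter:

- The median window at position *i* covers beats `[i − 50, i + 49]`,
  truncated at the series edges — no padding is fabricated.
- The median is computed **once, over the original series** (a single filter
  pass). Consequently no corrected value deviates from that reference median
  by more than the threshold; re-running the filter with the same reference
  flags nothing. Recomputing medians on the corrected series would not be
  idempotent and is not done.
- A deviation of exactly 10 bpm is *not* an error (strict inequality).

A centered median tracks smooth monotone HR changes almost exactly, so
physiological accelerations are not clipped unless their peak is sharp; only
a handful of beats at sharp peaks are ever flagged, which the 30% window
exclusion (below) tolerates.

### Carry-over range

Windows of 30 s advance in 2-s steps on a grid anchored at the first beat;
windows are half-open `[t, t+30)` so boundary beats are counted once. The
range of window *k* ≥ 1 is `max_k − min(min_k, min_{k−1})` with the **raw**
minimum of the immediately preceding window — the carry is non-recursive. A
recursive carry (propagating the carried minimum) would never release after
one sustained acceleration; the single-window look-back captures
accelerations lasting beyond 30 s while recovering once HR returns to
baseline. If the previous window holds no beats the current minimum is used.

Exclusion rule: the expected beat count is `E = mean_hr × 30 / 60`; a window
is invalid when `n_corrected / E ≥ 0.30` (strict `<` keeps it valid) or when
it holds fewer than two beats. A record shorter than one window yields a
single truncated window flagged invalid.

### Window–annotation pairing and classification

Annotations are up-sampled to the 2-s grid by zero-order hold (labels are
categorical; any smoother interpolation is meaningless). A 30-s window
generally straddles two scoring epochs; the canonical pipeline pairs each
window with the annotation at the **window midpoint**, the state occupying
the majority of the window (`window_labels`). Grid points outside the
annotated span are UNSCORED.

ROC calibration pools valid AS/QS windows (AWAKE and UNSCORED are dropped;
per-subject inverse-count weighting is available as an option). The AUC is
the Mann–Whitney probability that a random AS range exceeds a random QS
range with ties counting one half; the operating point maximizes Youden's
J = sensitivity + specificity − 1, ties broken toward the lower threshold.
Classification is `range > threshold → AS`, strict, so a range exactly at
the threshold is QS; invalid windows are UNSCORED. The fixed thresholds are
stratified by postmenstrual age: 18 bpm below 37 weeks, 20 bpm at or above,
with no default when PMA is unknown.

### EEG delta power

- **ECG interference attenuation**: for each channel and 0.5 Hz bin, a
  complex regression coefficient of the EEG on the ECG is estimated across
  non-overlapping 2-s Hann-tapered segments and the predicted component is
  subtracted from the channel's full-record spectrum. Bins act only where
  the magnitude-squared coherence exceeds the standard segment-count
  significance threshold `1 − α^{1/(K−1)}`; a channel with no bin passing a
  Bonferroni-adjusted gate is left untouched, so channels free of cardiac
  artifact are bit-identical to their input.
- **Referencing**: the mean complex coefficient across channels is
  subtracted per frequency bin. By linearity this equals time-domain
  common-average referencing to machine precision (verified to 1e−10),
  and reduces volume-conducted components shared across the array.
- **Montage**: 14 longitudinal bipolar, double-distance derivations
  (Fp1-T3, T3-O1, Fp2-T4, T4-O2, Fp1-C3, C3-O1, Fp2-C4, C4-O2, T3-C3,
  C3-Cz, Cz-C4, C4-T4, Fz-Cz, Cz-Pz). High-density electrode layouts map to
  the 10-20 labels through a user-supplied text config (`PAIR`/`MAP` lines).
- **Welch spectra**: Hann taper, 50% overlap, segment length
  `fs / 0.5 Hz` = 500 samples, density scaling (so the PSD integrates to
  the variance; the white-noise Parseval check holds within 5%). Taper and
  overlap are field-standard defaults and configurable.
- **Delta power**: median of the natural-log power over the bins in
  0.5–4 Hz, endpoints inclusive (8 bins at 0.5 Hz resolution). The median
  is robust to residual artifact in single bins; the log base only scales
  mixed-model estimates, so estimates here are in natural-log units.
- **Clean-segment selection** is a deliberately simple stand-in for
  dedicated neonatal artifact detectors: the record is scored per 2-s block
  by the 95th percentile of absolute amplitude per channel, and the
  contiguous window minimizing the worst block score across channels is
  returned (first window on ties).

### Group statistics

Per channel, a linear mixed-effects model relates per-subject, per-state
median log delta power to state (coded so a positive estimate means higher
delta power in QS), sex and PMA (weeks, linear) as fixed effects, with a
random intercept per subject; an alternative adds a random slope for state.
Both are fit by **maximum likelihood** — BICs are only comparable across
random-effects structures under a common likelihood definition — and the
lower-BIC model is reported. With one observation per subject and state the
random-slope variance is weakly identified; failed or non-finite fits fall
back to the intercept model, which is also what the BIC prefers in
simulation. P-values are **Wald tests** on the state coefficient (the
likelihood-ratio alternative is not implemented); with 50 subjects the
ML/Wald combination is mildly anticonservative (observed type-I ≈ 5–7% at
nominal 5% over large simulations). Benjamini–Hochberg step-up adjustment
is applied across the 14 channels at FDR 0.05.

The package ships the published 14-channel raw p-values for this montage as
a reference input (`stats.REFERENCE_CHANNEL_PVALUES`); the underlying
recordings are restricted, so these serve to validate the correction and
counting steps, not to re-estimate the models.

## Synthetic data: what it emulates, and what it does not

`SyntheticConfig` defaults define the simulated study conditions:

| parameter | default | meaning |
|---|---|---|
| `total_duration` | 3600 s | one bedside session |
| `mean_state_dwell` | 300 s | mean AS/QS bout (60 s + exponential, ≥ 2 epochs) |
| `baseline_hr` | 150 bpm | neonatal resting rate |
| `qs_fluct_sd` | 2 bpm | AR(1) HR fluctuation SD (~5 s correlation time) |
| `as_accel_magnitude` | 30 bpm | acceleration peak height |
| `as_accel_rate` | 3 /min | movement-burst rate (coverage saturates) |
| `ectopic_rate` | 1 /min | ±25 bpm single-beat spikes |
| `delta_ratio_qs_as` | 1.5 | QS delta-amplitude multiplier |
| `eeg_ecg_leak` | 0 | ECG gain into temporal electrodes |

Design choices: AS accelerations are a renewal process of piecewise-linear
bursts (rise 10–20 s, decay 20–40 s) filling each bout nearly end to end,
because the movements that define AS are continuous or periodic within every
scored epoch. Bursts start no earlier than 15 s into a bout and end before
it, so windows whose midpoint lies in QS never contain one — this is what
makes the designed regimes (QS ranges well under 18 bpm, acceleration
windows above it) hold exactly rather than approximately. Ectopic spikes
are injected into the HR values with the ground-truth beat times left
clean, so detector round trips and correction-flag checks have exact
oracles. EEG channels carry independent delta-band noise with state-scaled
amplitude plus a weaker 4–30 Hz component; a per-subject offset on log
delta power plays the role of the random intercept the mixed models
estimate. All randomness flows from one integer seed through numpy's PCG64.

What the generator does **not** emulate — and what passing tests therefore
do not establish for real data: respiration and its coupling to HR, true
beat-to-beat HRV spectra, arrhythmias beyond single ectopics, EEG
discontinuity (tracé alternant), electrode artifacts, or any annotation
noise from human scoring. The synthetic-recovery results (AUC ≈ 0.98,
accuracy ≈ 0.97 on the default conditions) characterize the pipeline's
correctness under its own assumptions, not expected clinical performance;
the published cohort-level figures (AUC ≈ 0.88, thresholds ≈ 18.6 bpm) come
from restricted recordings that cannot be regenerated here.

## Problem sizes

The test suite and acceptance script use one simulated hour per recovery
run (~9,500 beats, ~1,800 windows), 12-minute EEG segments for the spectral
contrast, and 100 replicates of 50 subjects for mixed-model calibration —
sizes at which every quantity is stable to the tolerances asserted while
the whole suite completes in about a minute.

## Known limitations

- The Hilbert-phase detector interprets a cited method whose exact filter
  band and refinement are unpublished; the implementation is documented
  above, not asserted as a reproduction.
- "Window size of 100 beats per minute" in the source description is read
  as a 100-beat window (a median over HR samples is naturally indexed in
  beats; 100 beats ≈ 40 s at neonatal rates).
- Whether the carry-over uses the raw or the carried previous minimum is
  ambiguous in prose; the non-recursive (raw) reading is implemented.
- Whether the first, partially-filled window participates in classification
  is unspecified; here a truncated-record window is flagged invalid.
- EDF files can be read (via `mne`) but not written; plain CSV is the
  interchange format for all outputs.
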