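"""Seeded generators for neonatal sleep-state sequences, HR/ECG traces and EEG.

The cohort recordings behind this method are IRB-restricted, so the package
ships a generator that reproduces the *statistical structure* the pipeline
assumes: two-state behavioral dynamics on a 30-s scoring grid; quiet-sleep
heart rate as small autocorrelated fluctuations around a stable baseline;
active-sleep heart rate with superimposed large accelerations that can outlast
a single 30-s window; ECG-like waveforms built from a QRS template at known
beat times; and multichannel EEG whose delta-band amplitude is elevated
during quiet sleep, with an optional ECG leak into a subset of electrodes.

All randomness flows from a single integer seed through numpy's PCG64
generator (``numpy.random.default_rng``), so outputs are bit-for-bit
reproducible across platforms.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .ecg import ECGTrace, HeartRateSeries, beats_to_hr, BeatSeries
from .eeg import EEGRecording
from .sleep import AS, QS, StateAnnotation

__all__ = [
    "SyntheticConfig", "MONOPOLAR_ELECTRODES",
    "gen_states", "gen_hr", "gen_ecg", "gen_eeg", "gen_delta_records",
]

#: 10-20 electrodes sufficient to derive the 14-channel bipolar montage.
MONOPOLAR_ELECTRODES: tuple[str, ...] = (
    "Fp1", "Fp2", "C3", "C4", "Cz", "T3", "T4", "O1", "O2", "Fz", "Pz")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults define the simulated study conditions.

    Attributes
    ----------
    seed : int
        Master seed; fixes every output bit-for-bit.
    total_duration : float
        Recording length in seconds (default 3600, one bedside session).
    mean_state_dwell : float
        Mean AS/QS bout length in seconds (default 300); bouts are
        60 s + exponential so no bout is shorter than two scoring epochs.
    baseline_hr : float
        Resting neonatal heart rate, bpm (default 150).
    qs_fluct_sd : float
        Standard deviation of the AR(1) heart-rate fluctuations, bpm
        (default 2; keeps quiet-sleep window ranges well below 18 bpm).
    as_accel_magnitude : float
        Peak height of active-sleep acceleration events, bpm (default 30).
    as_accel_rate : float
        Acceleration events per minute of active sleep (default 3; with
        events lasting 30-60 s this makes accelerations quasi-continuous
        during AS, mirroring the continual movements that define the state).
    ectopic_rate : float
        Erroneous-beat spikes per minute, injected into the HR series as
        single-beat ±25 bpm excursions (default 1).
    eeg_fs : float
        EEG/ECG sampling rate, Hz (default 250).
    delta_ratio_qs_as : float
        Multiplicative increase of delta-band EEG amplitude during QS
        (default 1.5; must exceed 1).
    eeg_ecg_leak : float
        Gain of the ECG leaking additively into the temporal electrodes
        (default 0, i.e. no cardiac artifact).
    """

    seed: int = 0
    total_duration: float = 3600.0
    mean_state_dwell: float = 300.0
    baseline_hr: float = 150.0
    qs_fluct_sd: float = 2.0
    as_accel_magnitude: float = 30.0
    as_accel_rate: float = 3.0
    ectopic_rate: float = 1.0
    eeg_fs: float = 250.0
    delta_ratio_qs_as: float = 1.5
    eeg_ecg_leak: float = 0.0

    def __post_init__(self) -> None:
        if self.total_duration < 2 * self.mean_state_dwell:
            raise ValueError("total_duration must cover at least two mean dwells")
        if self.mean_state_dwell < 60.0:
            raise ValueError("mean_state_dwell must be at least 60 s")
        if self.delta_ratio_qs_as <= 1.0:
            raise ValueError("delta_ratio_qs_as must exceed 1")


def _rng(cfg_or_seed) -> np.random.Generator:
    seed = cfg_or_seed.seed if isinstance(cfg_or_seed, SyntheticConfig) else cfg_or_seed
    return np.random.default_rng(seed)


def gen_states(cfg: SyntheticConfig,
               rng: np.random.Generator | None = None) -> StateAnnotation:
    """Alternating AS/QS bouts with shifted-exponential dwell times.

    Each bout lasts ``60 + Exponential(mean_state_dwell - 60)`` seconds,
    rounded to the 30-s scoring grid (minimum two epochs), so epochs are never
    pure transitions.  The starting state is drawn at random.  The returned
    annotation is the ground truth (the generator scores exactly).
    """
    rng = rng or _rng(cfg)
    n_epochs = int(np.floor(cfg.total_duration / 30.0))
    state = AS if rng.random() < 0.5 else QS
    labels: list[str] = []
    while len(labels) < n_epochs:
        dwell = 60.0 + rng.exponential(cfg.mean_state_dwell - 60.0)
        k = max(2, int(round(dwell / 30.0)))
        labels.extend([state] * k)
        state = QS if state == AS else AS
    starts = 30.0 * np.arange(n_epochs)
    return StateAnnotation(starts, np.array(labels[:n_epochs]), epoch_len=30.0)


def _instantaneous_rate(states: StateAnnotation, cfg: SyntheticConfig,
                        rng: np.random.Generator, dt: float = 0.25):
    """Continuous instantaneous HR (bpm) on a ``dt`` grid."""
    duration = len(states) * states.epoch_len
    t = np.arange(0.0, duration, dt)
    n = t.size

    # AR(1) fluctuations with ~5 s correlation time, stationary SD qs_fluct_sd
    tau = 5.0
    phi = np.exp(-dt / tau)
    innov_sd = cfg.qs_fluct_sd * np.sqrt(1.0 - phi ** 2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, cfg.qs_fluct_sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    rate = cfg.baseline_hr + x

    # Acceleration events inside AS bouts: linear rise 10-20 s, decay 20-40 s,
    # placed as a renewal process of movement bursts covering the bout nearly
    # end to end (the movements defining active sleep are continuous or
    # periodic).  Events start no earlier than half an analysis window (15 s)
    # into the bout and end before it does, so a 30-s window whose midpoint
    # lies in quiet sleep never sees an acceleration.  ``as_accel_rate`` sets
    # the end-to-start gap between bursts (mean cycle ~ 60/rate s, gap
    # floored at 5 s); near the bout end a final compressed event (shorter
    # decay) may be placed so bouts do not finish with a long quiet tail.
    onset_guard = 15.0
    mean_event = 45.0          # mean rise + mean decay
    gap_mean = max(60.0 / cfg.as_accel_rate - mean_event, 5.0)
    lab_at = states.labels[np.minimum((t // states.epoch_len).astype(int),
                                      len(states) - 1)]
    is_as = lab_at == AS
    edges = np.flatnonzero(np.diff(is_as.astype(int))) + 1
    bounds = np.concatenate([[0], edges, [n]])
    events = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if not is_as[a]:
            continue
        seg_end = t[a] + (b - a) * dt
        start = t[a] + onset_guard + rng.exponential(gap_mean)
        while seg_end - start >= 15.0:
            rise = rng.uniform(10.0, 20.0)
            if seg_end - start < rise + 5.0:
                rise = max(5.0, seg_end - start - 5.0)
            decay = min(rng.uniform(20.0, 40.0), seg_end - start - rise)
            events.append((start, rise, decay))
            rel = t - start
            bump = np.zeros(n)
            up = (rel >= 0) & (rel < rise)
            bump[up] = rel[up] / rise
            dn = (rel >= rise) & (rel < rise + decay)
            bump[dn] = 1.0 - (rel[dn] - rise) / decay
            rate = rate + cfg.as_accel_magnitude * bump
            start = start + rise + decay + rng.exponential(gap_mean)
    return t, rate, events


def gen_hr(states: StateAnnotation, cfg: SyntheticConfig,
           rng: np.random.Generator | None = None
           ) -> tuple[HeartRateSeries, np.ndarray, list[tuple[float, float, float]]]:
    """Beat-to-beat HR for a state sequence.

    Returns ``(series, true_beat_times, events)`` where ``events`` lists the
    acceleration events as ``(start_s, rise_s, decay_s)`` ground truth.  Beat
    times come from integrating the instantaneous rate (a beat per unit of
    accumulated phase).  Ectopic spikes are injected afterwards into the HR
    values of isolated beats (±25 bpm), leaving the ground-truth beat times
    clean; the median-filter correction stage is expected to find exactly
    these.
    """
    rng = rng or _rng(cfg)
    t, rate, events = _instantaneous_rate(states, cfg, rng)
    dt = t[1] - t[0]
    phase = np.concatenate([[0.0], np.cumsum(rate / 60.0 * dt)])
    t_edges = np.concatenate([t, [t[-1] + dt]])
    n_beats = int(np.floor(phase[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), phase, t_edges)

    series = beats_to_hr(BeatSeries(beat_times))
    hr = series.hr.copy()
    n_ect = rng.poisson(cfg.ectopic_rate * (t[-1] + dt) / 60.0)
    if n_ect > 0 and hr.size > 2:
        idx = rng.choice(np.arange(1, hr.size - 1), size=min(n_ect, hr.size - 2),
                         replace=False)
        sign = rng.choice([-1.0, 1.0], size=idx.size)
        hr[idx] = np.maximum(hr[idx] + 25.0 * sign, 30.0)
    return (HeartRateSeries(series.times, hr, np.zeros(hr.size, dtype=bool)),
            beat_times, events)


def _qrs_template(fs: float) -> np.ndarray:
    """Asymmetric biphasic QRS-like pulse of ~80 ms, maximum at its center."""
    t = np.arange(-0.04, 0.04 + 1.0 / fs, 1.0 / fs)
    r = np.exp(-0.5 * (t / 0.008) ** 2)
    s = -0.4 * np.exp(-0.5 * ((t - 0.018) / 0.010) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.015) / 0.008) ** 2)
    return r + s + q


def gen_ecg(beat_times: np.ndarray, fs: float = 250.0,
            duration: float | None = None, snr_db: float | None = 10.0,
            rng: np.random.Generator | int | None = None) -> ECGTrace:
    """ECG trace: a fixed QRS template at each beat time plus white noise.

    ``snr_db=None`` produces a noise-free trace.  An empty beat list yields
    pure noise.  The template's maximum falls exactly on the beat time, so
    detector round-trips can be scored against the input times.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if duration is None:
        duration = (beat_times[-1] + 1.0) if beat_times.size else 10.0
    n = int(round(duration * fs))
    x = np.zeros(n)
    tpl = _qrs_template(fs)
    half = tpl.size // 2
    for bt in beat_times:
        c = int(round(bt * fs))
        a, b = c - half, c - half + tpl.size
        ta, tb = max(0, -a), tpl.size - max(0, b - n)
        a, b = max(0, a), min(n, b)
        if a < b:
            x[a:b] += tpl[ta:tb]
    if snr_db is not None:
        sig_power = np.mean(x ** 2) if beat_times.size else 1.0
        noise_sd = np.sqrt(sig_power / 10.0 ** (snr_db / 10.0))
        x = x + rng.normal(0.0, noise_sd, size=n)
    return ECGTrace(x, fs=fs)


def _band_noise(rng, n, fs, lo, hi):
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, rng.standard_normal(n))


def gen_eeg(states: StateAnnotation, cfg: SyntheticConfig,
            ecg: ECGTrace | None = None,
            subject_intercept: float = 0.0,
            duration: float | None = None,
            rng: np.random.Generator | None = None) -> EEGRecording:
    """Multichannel EEG whose delta amplitude is elevated during quiet sleep.

    Each monopolar electrode carries independent delta-band (0.5–4 Hz) noise
    whose amplitude is multiplied by ``delta_ratio_qs_as`` during QS epochs,
    plus a weaker broadband (4–30 Hz) component.  ``subject_intercept`` is an
    additive offset on log delta power (the subject-level random effect the
    mixed models estimate): the delta amplitude is scaled by
    ``exp(subject_intercept / 2)``.  With ``eeg_ecg_leak > 0`` and an ECG
    supplied, ``leak × ecg`` is added to the temporal electrodes (T3, T4).
    """
    rng = rng or _rng(cfg)
    fs = cfg.eeg_fs
    total = len(states) * states.epoch_len
    if duration is None:
        duration = total
    duration = min(duration, total)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    lab_at = states.labels[np.minimum((t // states.epoch_len).astype(int),
                                      len(states) - 1)]
    amp = np.where(lab_at == QS, cfg.delta_ratio_qs_as, 1.0)
    amp = amp * np.exp(subject_intercept / 2.0)

    base_delta_uv = 20.0
    data = np.empty((len(MONOPOLAR_ELECTRODES), n))
    for ch in range(len(MONOPOLAR_ELECTRODES)):
        delta = _band_noise(rng, n, fs, 0.5, 4.0)
        broad = _band_noise(rng, n, fs, 4.0, 30.0)
        data[ch] = base_delta_uv * amp * delta + 6.0 * broad
    if ecg is not None and cfg.eeg_ecg_leak != 0.0:
        leak = cfg.eeg_ecg_leak * ecg.samples[:n]
        for name in ("T3", "T4"):
            data[MONOPOLAR_ELECTRODES.index(name)] += leak
    return EEGRecording(data, list(MONOPOLAR_ELECTRODES), fs)


def gen_delta_records(n_subjects: int,
                      channels,
                      state_effect: float,
                      intercept_sd: float = 0.3,
                      resid_sd: float = 0.1,
                      sex_effect: float = 0.0,
                      pma_effect: float = 0.0,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Delta-power records straight from the mixed model's generative form.

    One record per subject × channel × state with
    ``delta = 2 + b_subj + state_effect·[QS] + sex_effect·[F] +
    pma_effect·(PMA − 38) + ε``, where ``b_subj ~ N(0, intercept_sd²)`` and
    ``ε ~ N(0, resid_sd²)``.  PMA uniform on [34, 42] weeks, sex balanced at
    random — the simulated cohort's study window.  Used for power and type-I
    calibration of the group-statistics stage without simulating raw EEG.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(channels, (int, np.integer)):
        from .stats import MONTAGE_CHANNELS
        channels = MONTAGE_CHANNELS[:channels]
    rows = []
    for s in range(n_subjects):
        b = rng.normal(0.0, intercept_sd)
        pma = rng.uniform(34.0, 42.0)
        sex = "F" if rng.random() < 0.5 else "M"
        for ch in channels:
            for state in (AS, QS):
                y = (2.0 + b + state_effect * (state == QS)
                     + sex_effect * (sex == "F")
                     + pma_effect * (pma - 38.0)
                     + rng.normal(0.0, resid_sd))
                rows.append({"subject_id": f"S{s:03d}", "channel": ch,
                             "state": state, "delta_power": y,
                             "sex": sex, "pma_weeks": pma})
    return pd.DataFrame(rows)
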