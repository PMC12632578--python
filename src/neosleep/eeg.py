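"""EEG delta power: ECG-interference attenuation, frequency-domain common-average
referencing, bipolar montage, Welch spectra, and median log delta power.

Quiet sleep in preterm infants is dominated by discontinuous, high-amplitude
slow activity (tracé alternant / tracé discontinu), so spectral power in the
delta band (0.5–4 Hz) is the cortical signature used to validate the
HR-derived sleep labels.  The summary statistic per channel is the *median of
the log-transformed* Welch spectral power across the delta bins — the median
is robust to residual artifact in single bins, and the natural log puts the
mixed-model contrasts on a ratio scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from scipy.signal.windows import hann

from .config import DEFAULT_CONFIG, ProcessingConfig
from .ecg import ECGTrace

__all__ = [
    "EEGRecording", "MontageMap", "PowerSpectrum",
    "DEFAULT_BIPOLAR_PAIRS",
    "attenuate_ecg_interference", "subtract_global_average", "to_bipolar",
    "welch_spectrum", "delta_power", "select_clean_segment",
]

#: Longitudinal bipolar, double-distance montage (14 derivations).
DEFAULT_BIPOLAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "T3"), ("T3", "O1"), ("Fp2", "T4"), ("T4", "O2"),
    ("Fp1", "C3"), ("C3", "O1"), ("Fp2", "C4"), ("C4", "O2"),
    ("T3", "C3"), ("C3", "Cz"), ("Cz", "C4"), ("C4", "T4"),
    ("Fz", "Cz"), ("Cz", "Pz"),
)


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    channel_labels: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_labels = list(self.channel_labels)
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("one label per channel required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class MontageMap:
    """Bipolar derivation plan: ordered (anode, cathode) label pairs plus a
    lookup from 10-20 label to source-channel index in the recording."""

    pairs: tuple[tuple[str, str], ...] = DEFAULT_BIPOLAR_PAIRS
    electrode_lookup: dict[str, int] | None = None

    def resolve(self, eeg: EEGRecording, label: str) -> int:
        if self.electrode_lookup is not None and label in self.electrode_lookup:
            return self.electrode_lookup[label]
        try:
            return eeg.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"electrode label {label!r} not resolvable in recording")

    @classmethod
    def from_config_text(cls, text: str) -> "MontageMap":
        """Parse ``PAIR anode cathode`` and ``MAP label index`` lines."""
        pairs: list[tuple[str, str]] = []
        lookup: dict[str, int] = {}
        for line in text.splitlines():
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0].upper() == "PAIR" and len(parts) == 3:
                pairs.append((parts[1], parts[2]))
            elif parts[0].upper() == "MAP" and len(parts) == 3:
                lookup[parts[1]] = int(parts[2])
            else:
                raise ValueError(f"unparseable montage line: {line!r}")
        return cls(pairs=tuple(pairs) or DEFAULT_BIPOLAR_PAIRS,
                   electrode_lookup=lookup or None)


@dataclass
class PowerSpectrum:
    """Welch power spectral density per channel on a uniform frequency grid."""

    freqs: np.ndarray            # Hz, starting at 0, spacing = welch_resolution
    power: np.ndarray            # channels x freqs, µV²/Hz
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))


def _segment_ffts(x: np.ndarray, nperseg: int) -> np.ndarray:
    """Hann-tapered rFFTs of consecutive non-overlapping segments."""
    n_seg = x.shape[-1] // nperseg
    if n_seg == 0:
        raise ValueError("record shorter than one segment")
    segs = x[..., : n_seg * nperseg].reshape(*x.shape[:-1], n_seg, nperseg)
    return np.fft.rfft(segs * hann(nperseg), axis=-1)


def attenuate_ecg_interference(eeg: EEGRecording, ecg: ECGTrace,
                               cfg: ProcessingConfig = DEFAULT_CONFIG,
                               alpha: float = 0.05) -> EEGRecording:
    """Remove the ECG-predictable component of each EEG channel, per frequency.

    For every channel and frequency bin, a complex regression coefficient of
    the EEG segment spectrum on the ECG segment spectrum is estimated across
    non-overlapping tapered segments; where the magnitude-squared coherence is
    significant (threshold ``1 - alpha**(1/(K-1))`` for K segments, with a
    Bonferroni-style channel gate across bins) the predicted component
    ``beta * ECG`` is subtracted from the channel's full-record spectrum.
    Channels with no significant ECG coherence anywhere pass through unchanged.
    """
    if eeg.n_samples != ecg.samples.size:
        raise ValueError("EEG and ECG must be time-aligned with equal length")
    if abs(eeg.fs - ecg.fs) > 1e-9:
        raise ValueError("EEG and ECG must share a sampling rate")

    nperseg = int(round(eeg.fs / cfg.welch_resolution_hz))
    E = _segment_ffts(eeg.data, nperseg)           # ch x K x F
    C = _segment_ffts(ecg.samples, nperseg)        # K x F
    K = C.shape[0]
    if K < 3:
        raise ValueError("need at least 3 segments to estimate coherence")

    Scc = np.mean(np.abs(C) ** 2, axis=0)                        # F
    See = np.mean(np.abs(E) ** 2, axis=1)                        # ch x F
    Sec = np.mean(E * np.conj(C), axis=1)                        # ch x F
    with np.errstate(invalid="ignore", divide="ignore"):
        coh2 = np.abs(Sec) ** 2 / (See * Scc)
        beta = Sec / Scc
    coh2 = np.nan_to_num(coh2)
    beta = np.nan_to_num(beta)

    n_bins = Scc.size
    bin_thresh = 1.0 - alpha ** (1.0 / (K - 1))
    gate_thresh = 1.0 - (alpha / n_bins) ** (1.0 / (K - 1))
    channel_active = (coh2 > gate_thresh).any(axis=1)

    out = eeg.data.copy()
    if channel_active.any():
        seg_freqs = np.fft.rfftfreq(nperseg, d=1.0 / eeg.fs)
        full_E = np.fft.rfft(eeg.data, axis=-1)
        full_C = np.fft.rfft(ecg.samples)
        full_freqs = np.fft.rfftfreq(eeg.n_samples, d=1.0 / eeg.fs)
        for ch in np.flatnonzero(channel_active):
            b = np.where(coh2[ch] > bin_thresh, beta[ch], 0.0 + 0.0j)
            b_full = (np.interp(full_freqs, seg_freqs, b.real)
                      + 1j * np.interp(full_freqs, seg_freqs, b.imag))
            out[ch] = np.fft.irfft(full_E[ch] - b_full * full_C, n=eeg.n_samples)
    return EEGRecording(out, eeg.channel_labels, eeg.fs)


def subtract_global_average(eeg: EEGRecording) -> EEGRecording:
    """Common-average referencing performed in the frequency domain.

    The mean complex spectral coefficient across channels is subtracted from
    every channel at each bin; by linearity of the Fourier transform this
    equals subtracting the time-domain global average, and the cross-channel
    mean of the output is zero at every bin.  Used to reduce volume-conducted
    components shared by all electrodes.
    """
    if eeg.n_channels < 2:
        raise ValueError("global-average referencing needs at least 2 channels")
    spec = np.fft.rfft(eeg.data, axis=-1)
    spec -= spec.mean(axis=0, keepdims=True)
    out = np.fft.irfft(spec, n=eeg.n_samples, axis=-1)
    return EEGRecording(out, eeg.channel_labels, eeg.fs)


def to_bipolar(eeg: EEGRecording, montage: MontageMap | None = None) -> EEGRecording:
    """Re-derive the recording as bipolar channels ``anode − cathode``."""
    montage = montage or MontageMap()
    rows, labels = [], []
    for anode, cathode in montage.pairs:
        ia = montage.resolve(eeg, anode)
        ic = montage.resolve(eeg, cathode)
        rows.append(eeg.data[ia] - eeg.data[ic])
        labels.append(f"{anode}-{cathode}")
    return EEGRecording(np.vstack(rows), labels, eeg.fs)


def welch_spectrum(eeg: EEGRecording,
                   cfg: ProcessingConfig = DEFAULT_CONFIG) -> PowerSpectrum:
    """Welch PSD with Hann taper, 50% overlap, and ``welch_resolution_hz`` bins.

    The segment length is ``fs / welch_resolution_hz`` samples (500 at 250 Hz
    for 0.5 Hz resolution).  Density scaling, so the integral of the PSD over
    frequency approximates the signal variance (Parseval).
    """
    nperseg = int(round(eeg.fs / cfg.welch_resolution_hz))
    if eeg.n_samples < nperseg:
        raise ValueError("record shorter than one Welch segment")
    freqs, pxx = welch(eeg.data, fs=eeg.fs, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2, detrend="constant",
                       scaling="density", axis=-1)
    return PowerSpectrum(freqs, pxx, list(eeg.channel_labels))


def delta_power(ps: PowerSpectrum,
                cfg: ProcessingConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Median of log-transformed power over the delta band, per channel.

    Band endpoints are inclusive on the frequency grid (8 bins for 0.5–4 Hz
    at 0.5 Hz resolution).  Natural logarithm.
    """
    lo, hi = cfg.delta_band
    band = (ps.freqs >= lo - 1e-9) & (ps.freqs <= hi + 1e-9)
    if not band.any():
        raise ValueError("frequency grid does not cover the delta band")
    p = ps.power[:, band]
    if np.any(p <= 0):
        raise ValueError("nonpositive spectral power in the delta band")
    return np.median(np.log(p), axis=1)


def select_clean_segment(eeg: EEGRecording, duration: float,
                         block_s: float = 2.0) -> EEGRecording:
    """Pick the contiguous window with the least high-amplitude activity.

    The record is scored in ``block_s`` blocks by the 95th percentile of
    absolute amplitude per channel; the returned window of length ``duration``
    minimizes the maximum score across its blocks and channels (first window
    on ties).  This is a deliberately simple artifact-avoidance criterion
    standing in for dedicated neonatal artifact detectors.
    """
    n_need = int(round(duration * eeg.fs))
    if eeg.n_samples < n_need:
        raise ValueError("record shorter than the requested duration")
    if eeg.n_samples == n_need:
        return EEGRecording(eeg.data.copy(), eeg.channel_labels, eeg.fs)

    blk = int(round(block_s * eeg.fs))
    n_blocks = eeg.n_samples // blk
    scores = np.percentile(
        np.abs(eeg.data[:, : n_blocks * blk]).reshape(eeg.n_channels, n_blocks, blk),
        95, axis=-1).max(axis=0)                                  # worst channel per block
    win_blocks = max(1, int(np.ceil(n_need / blk)))
    if n_blocks < win_blocks:
        start = 0
    else:
        win_scores = np.array([scores[i:i + win_blocks].max()
                               for i in range(n_blocks - win_blocks + 1)])
        start = int(np.argmin(win_scores)) * blk
    start = min(start, eeg.n_samples - n_need)
    return EEGRecording(eeg.data[:, start:start + n_need].copy(),
                        eeg.channel_labels, eeg.fs)
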