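"""Readers and writers for the pipeline's plain-text formats (CSV) and EDF.

CSV layouts
-----------
ECG:          time_s, amplitude
heart rate:   beat_time_s, hr_bpm, corrected (0/1)
range:        window_start_s, range_bpm, valid, mean_hr, n_beats, n_corrected
annotations:  epoch_start_s, label  (AS / QS / AWAKE / UNSCORED)
EEG:          time_s column plus one column per channel label
delta power:  subject_id, channel, state, delta_power, sex, pma_weeks

EDF reading (optional) goes through ``mne``; there is no EDF writer here.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import ECGTrace, HeartRateSeries
from .eeg import EEGRecording
from .ranges import RangeSeries
from .sleep import StateAnnotation


def read_ecg_csv(path) -> ECGTrace:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("ECG CSV must contain at least two samples")
    fs = 1.0 / np.median(np.diff(t))
    return ECGTrace(x, fs=float(round(fs, 6)), t0=float(t[0]))


def write_ecg_csv(path, ecg: ECGTrace) -> None:
    pd.DataFrame({"time_s": ecg.times, "amplitude": ecg.samples}).to_csv(
        path, index=False)


def read_ecg_edf(path, channel: str | None = None) -> ECGTrace:
    """Read the ECG signal from an EDF file (first channel whose label
    contains 'ECG' or 'EKG', case-insensitive, unless named explicitly)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channel is None:
        cands = [ch for ch in raw.ch_names
                 if "ECG" in ch.upper() or "EKG" in ch.upper()]
        if not cands:
            raise ValueError("no channel labeled ECG/EKG in EDF file")
        channel = cands[0]
    data = raw.get_data(picks=[channel])[0]
    return ECGTrace(data, fs=float(raw.info["sfreq"]))


def read_eeg_edf(path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(raw.get_data() * 1e6, list(raw.ch_names),
                        float(raw.info["sfreq"]))


def read_eeg_csv(path) -> EEGRecording:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    fs = 1.0 / np.median(np.diff(t))
    labels = list(df.columns[1:])
    return EEGRecording(df.iloc[:, 1:].to_numpy(dtype=float).T, labels,
                        float(round(fs, 6)))


def write_eeg_csv(path, eeg: EEGRecording) -> None:
    out = pd.DataFrame(eeg.data.T, columns=eeg.channel_labels)
    out.insert(0, "time_s", np.arange(eeg.n_samples) / eeg.fs)
    out.to_csv(path, index=False, float_format="%.4f")


def write_hr_csv(path, hr: HeartRateSeries) -> None:
    hr.to_frame().to_csv(path, index=False)


def read_hr_csv(path) -> HeartRateSeries:
    df = pd.read_csv(path)
    return HeartRateSeries(df["beat_time_s"].to_numpy(float),
                           df["hr_bpm"].to_numpy(float),
                           df["corrected"].to_numpy().astype(bool))


def write_range_csv(path, rs: RangeSeries) -> None:
    rs.to_frame().to_csv(path, index=False)


def read_range_csv(path) -> RangeSeries:
    df = pd.read_csv(path)
    return RangeSeries(df["window_start_s"].to_numpy(float),
                       df["range_bpm"].to_numpy(float),
                       df["valid"].to_numpy().astype(bool),
                       df["mean_hr"].to_numpy(float),
                       df["n_beats"].to_numpy(int),
                       df["n_corrected"].to_numpy(int))


def write_annotation_csv(path, ann: StateAnnotation) -> None:
    ann.to_frame().to_csv(path, index=False)


def read_annotation_csv(path, epoch_len: float | None = None) -> StateAnnotation:
    df = pd.read_csv(path)
    starts = df["epoch_start_s"].to_numpy(float)
    if epoch_len is None:
        epoch_len = float(np.median(np.diff(starts))) if starts.size > 1 else 30.0
    return StateAnnotation(starts, df["label"].to_numpy(dtype="U8"), epoch_len)


def read_delta_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "channel", "state", "delta_power"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"delta-power CSV missing columns: {sorted(missing)}")
    return df


def read_montage_config(path):
    from .eeg import MontageMap

    return MontageMap.from_config_text(Path(path).read_text())
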