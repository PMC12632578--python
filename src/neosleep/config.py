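"""Processing configuration: every numeric constant of the pipeline in one audited place."""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ProcessingConfig:
    """Numeric constants of the HR-range / EEG delta-power pipeline.

    Parameters
    ----------
    median_window_beats : int
        Length, in beats, of the centered running-median window used to flag
        erroneous beats (default 100 beats, roughly 40 s at neonatal rates).
    dev_threshold_bpm : float
        A beat whose HR deviates by *more than* this many bpm from the running
        median is flagged as erroneous and replaced by the median (default 10).
    window_s, step_s : float
        Sliding analysis window length and advance (default 30 s / 2 s).
    max_corrected_frac : float
        A window is excluded from range analysis when the fraction of corrected
        beats — relative to the expected beat count implied by the window's mean
        HR — reaches this value (default 0.30; the rule is strict ``<``).
    delta_band : (float, float)
        Delta frequency band in Hz, endpoints inclusive on the Welch grid
        (default 0.5–4 Hz).
    welch_resolution_hz : float
        Frequency resolution of the Welch periodogram (default 0.5 Hz, i.e.
        2-s segments at 250 Hz).
    pma_split_weeks : float
        Postmenstrual age (weeks) separating the immature (< split) from the
        mature (>= split) threshold group (default 37).
    threshold_immature_bpm, threshold_mature_bpm : float
        HR-range cut points (bpm) applied below / at-or-above the PMA split
        (defaults 18 and 20).
    """

    median_window_beats: int = 100
    dev_threshold_bpm: float = 10.0
    window_s: float = 30.0
    step_s: float = 2.0
    max_corrected_frac: float = 0.30
    delta_band: tuple[float, float] = (0.5, 4.0)
    welch_resolution_hz: float = 0.5
    pma_split_weeks: float = 37.0
    threshold_immature_bpm: float = 18.0
    threshold_mature_bpm: float = 20.0

    def __post_init__(self) -> None:
        if self.median_window_beats < 1:
            raise ValueError("median_window_beats must be a positive count")
        for name in ("dev_threshold_bpm", "window_s", "step_s",
                     "welch_resolution_hz", "pma_split_weeks",
                     "threshold_immature_bpm", "threshold_mature_bpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.max_corrected_frac < 1.0:
            raise ValueError("max_corrected_frac must lie in (0, 1)")
        lo, hi = self.delta_band
        if not 0.0 < lo < hi:
            raise ValueError("delta_band must satisfy 0 < low < high")


DEFAULT_CONFIG = ProcessingConfig()
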