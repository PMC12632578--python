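"""Carry-over heart-rate range over a 30-s window sliding in 2-s steps.

The range statistic: for the first window it is simply max − min of the HR
values inside the window.  For every later window k it is

    range[k] = max_k − min(min_k, min_{k−1})

where ``min_{k−1}`` is the *raw* minimum of the immediately preceding window
(the carry is non-recursive).  Carrying the previous window's minimum keeps
the pre-acceleration baseline in view during sustained HR accelerations that
outlast a single 30-s window, so the statistic reflects the full excursion.

Windows are half-open ``[t, t+window_s)`` on a grid anchored at the first
beat.  A window is excluded (``valid=False``) when it holds fewer than two
beats or when the fraction of corrected beats — measured against the expected
beat count implied by the window's mean HR — reaches 30%.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ProcessingConfig
from .ecg import HeartRateSeries

__all__ = [
    "RangeSeries", "WindowStats",
    "window_stats", "carryover_range", "apply_exclusion", "compute_range_series",
]


@dataclass
class RangeSeries:
    """HR range per sliding window on the ``step_s`` grid."""

    window_starts: np.ndarray   # s, arithmetic grid with spacing step_s
    range_bpm: np.ndarray       # NaN where the window held no beats
    valid: np.ndarray
    mean_hr: np.ndarray
    n_beats: np.ndarray
    n_corrected: np.ndarray

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.range_bpm = np.asarray(self.range_bpm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.mean_hr = np.asarray(self.mean_hr, dtype=float)
        self.n_beats = np.asarray(self.n_beats, dtype=int)
        self.n_corrected = np.asarray(self.n_corrected, dtype=int)
        n = self.window_starts.size
        for name in ("range_bpm", "valid", "mean_hr", "n_beats", "n_corrected"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match window_starts")

    def __len__(self) -> int:
        return self.window_starts.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_start_s": self.window_starts,
            "range_bpm": self.range_bpm,
            "valid": self.valid.astype(int),
            "mean_hr": self.mean_hr,
            "n_beats": self.n_beats,
            "n_corrected": self.n_corrected,
        })


class WindowStats(NamedTuple):
    min_bpm: float
    max_bpm: float
    mean_hr: float
    n_beats: int
    n_corrected: int


def window_stats(hr: HeartRateSeries, t_start: float,
                 cfg: ProcessingConfig = DEFAULT_CONFIG) -> WindowStats:
    """Statistics over beats whose time lies in ``[t_start, t_start + window_s)``.

    An empty window returns ``n_beats = 0`` with NaN statistics; the caller
    marks such windows invalid.
    """
    lo = np.searchsorted(hr.times, t_start, side="left")
    hi = np.searchsorted(hr.times, t_start + cfg.window_s, side="left")
    vals = hr.hr[lo:hi]
    if vals.size == 0:
        return WindowStats(np.nan, np.nan, np.nan, 0, 0)
    return WindowStats(
        float(vals.min()), float(vals.max()), float(vals.mean()),
        int(vals.size), int(hr.corrected[lo:hi].sum()),
    )


def carryover_range(hr: HeartRateSeries,
                    cfg: ProcessingConfig = DEFAULT_CONFIG) -> RangeSeries:
    """Compute the carry-over HR range on the sliding-window grid.

    The grid starts at the first beat time and advances by ``cfg.step_s``;
    the last window is the last one fully inside the record (ending at or
    before the last beat time).  A record shorter than one window yields a
    single truncated window flagged invalid.

    A window with no beats gets ``range = NaN``; when the *previous* window
    is empty the carry falls back to the current window's own minimum.
    """
    if len(hr) == 0:
        raise ValueError("empty heart-rate series")
    t0, t_end = hr.times[0], hr.times[-1]
    n_win = int(np.floor((t_end - t0 - cfg.window_s) / cfg.step_s)) + 1
    truncated = n_win < 1
    if truncated:
        n_win = 1
    starts = t0 + cfg.step_s * np.arange(n_win)

    mins = np.full(n_win, np.nan)
    maxs = np.full(n_win, np.nan)
    means = np.full(n_win, np.nan)
    n_beats = np.zeros(n_win, dtype=int)
    n_corr = np.zeros(n_win, dtype=int)
    for k, ts in enumerate(starts):
        mins[k], maxs[k], means[k], n_beats[k], n_corr[k] = window_stats(hr, ts, cfg)

    rng = np.full(n_win, np.nan)
    for k in range(n_win):
        if n_beats[k] == 0:
            continue
        floor = mins[k]
        if k > 0 and n_beats[k - 1] > 0:
            floor = min(floor, mins[k - 1])   # raw previous-window minimum
        rng[k] = maxs[k] - floor

    valid = n_beats >= 2
    if truncated:
        valid[:] = False
    return RangeSeries(starts, rng, valid, means, n_beats, n_corr)


def apply_exclusion(rs: RangeSeries,
                    cfg: ProcessingConfig = DEFAULT_CONFIG) -> RangeSeries:
    """Invalidate windows with too many corrected beats.

    The expected beat count is ``E = mean_hr * window_s / 60``; the window
    stays valid only when ``n_corrected / E < cfg.max_corrected_frac`` (strict)
    and it holds at least two beats.
    """
    expected = rs.mean_hr * cfg.window_s / 60.0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(expected > 0, rs.n_corrected / expected, np.inf)
    valid = rs.valid & (rs.n_beats >= 2) & (frac < cfg.max_corrected_frac)
    return RangeSeries(rs.window_starts, rs.range_bpm, valid,
                       rs.mean_hr, rs.n_beats, rs.n_corrected)


def compute_range_series(hr: HeartRateSeries,
                         cfg: ProcessingConfig = DEFAULT_CONFIG) -> RangeSeries:
    """Carry-over range plus the corrected-beat window exclusion, in one call."""
    return apply_exclusion(carryover_range(hr, cfg), cfg)
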