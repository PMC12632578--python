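"""Sleep-state labels, annotation alignment, ROC calibration and classification.

Behavioral scoring labels 30-s epochs as active sleep (AS), quiet sleep (QS)
or AWAKE.  To compare with the HR-range series (2-s resolution) the labels
are up-sampled by zero-order hold.  A cut point on the range statistic is
calibrated by ROC analysis (AS = positive class, orientation
``range > threshold -> AS``) with the optimum at Youden's J, and the final
classifier applies a PMA-stratified threshold: 18 bpm below 37 weeks
postmenstrual age, 20 bpm at or above.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_array, check_is_fitted

from .config import DEFAULT_CONFIG, ProcessingConfig
from .ranges import RangeSeries

__all__ = [
    "AS", "QS", "AWAKE", "UNSCORED",
    "StateAnnotation", "SubjectMeta", "ROCResult",
    "upsample_annotations", "roc_calibrate", "select_threshold",
    "classify", "state_fractions", "SleepStateClassifier",
]

AS = "AS"
QS = "QS"
AWAKE = "AWAKE"
UNSCORED = "UNSCORED"
_LABELS = (AS, QS, AWAKE, UNSCORED)


@dataclass
class StateAnnotation:
    """Sleep-state labels on a uniform epoch grid.

    ``epoch_starts`` is arithmetic with spacing ``epoch_len`` (30 s for video
    scoring, 2 s after up-sampling); each epoch covers ``[start, start+len)``.
    """

    epoch_starts: np.ndarray
    labels: np.ndarray
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U8")
        if self.epoch_starts.size != self.labels.size:
            raise ValueError("epoch_starts and labels must have equal length")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        bad = set(np.unique(self.labels)) - set(_LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        d = np.diff(self.epoch_starts)
        if d.size and not np.allclose(d, self.epoch_len):
            if np.any(d < self.epoch_len - 1e-9):
                raise ValueError("overlapping epochs")
            raise ValueError("epoch_starts must be arithmetic with spacing epoch_len")

    def __len__(self) -> int:
        return self.epoch_starts.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch_start_s": self.epoch_starts, "label": self.labels})


@dataclass(frozen=True)
class SubjectMeta:
    """Subject metadata used for threshold stratification and group statistics."""

    subject_id: str
    pma_weeks: Optional[float] = None
    sex: Optional[str] = None   # "F" or "M"

    def __post_init__(self) -> None:
        if self.pma_weeks is not None and not 22.0 <= self.pma_weeks <= 46.0:
            raise ValueError("pma_weeks outside the plausible neonatal range [22, 46]")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")


@dataclass
class ROCResult:
    """Empirical ROC of the range statistic with the Youden-optimal cut point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutpoint: float
    sens_at_cut: float
    spec_at_cut: float


def upsample_annotations(ann: StateAnnotation, grid: np.ndarray) -> StateAnnotation:
    """Zero-order-hold label assignment onto a finer time grid.

    Each grid point takes the label of the epoch containing it (half-open
    epochs); grid points outside the annotated span become UNSCORED.  Labels
    are categorical, so piecewise-constant assignment is the only meaningful
    interpolation.
    """
    grid = np.asarray(grid, dtype=float)
    idx = np.searchsorted(ann.epoch_starts, grid + 1e-9, side="right") - 1
    out = np.full(grid.size, UNSCORED, dtype="U8")
    inside = idx >= 0
    covered = inside & (grid < ann.epoch_starts[np.clip(idx, 0, None)] + ann.epoch_len - 1e-9)
    out[covered] = ann.labels[idx[covered]]
    step = float(grid[1] - grid[0]) if grid.size > 1 else ann.epoch_len
    return StateAnnotation(grid, out, epoch_len=step)


def window_labels(ann: StateAnnotation, ranges: RangeSeries,
                  cfg: ProcessingConfig = DEFAULT_CONFIG) -> StateAnnotation:
    """Pair each sliding window with the behavioral state at its midpoint.

    A 30-s window generally straddles two scoring epochs; the state at the
    window midpoint is the state occupying the majority of the window, so the
    canonical pipeline compares each range value to the annotation sampled at
    ``window_start + window_s / 2``.  The returned labels are re-indexed on
    the window-start grid so they align with :func:`classify` output.
    """
    mid = ranges.window_starts + cfg.window_s / 2.0
    lab = upsample_annotations(ann, mid)
    step = float(ranges.window_starts[1] - ranges.window_starts[0]) \
        if len(ranges) > 1 else cfg.step_s
    return StateAnnotation(ranges.window_starts, lab.labels, epoch_len=step)


def _roc_points(values: np.ndarray, is_as: np.ndarray):
    """Sensitivity/specificity over the grid of observed range values.

    Orientation is ``value > threshold -> AS``:
    sens(th) = P(AS value > th), spec(th) = P(QS value <= th).
    """
    thresholds = np.unique(values)
    as_sorted = np.sort(values[is_as])
    qs_sorted = np.sort(values[~is_as])
    n_as, n_qs = as_sorted.size, qs_sorted.size
    sens = 1.0 - np.searchsorted(as_sorted, thresholds, side="right") / n_as
    spec = np.searchsorted(qs_sorted, thresholds, side="right") / n_qs
    return thresholds, sens, spec


def roc_calibrate(ranges: RangeSeries, labels: StateAnnotation,
                  sample_weight: Optional[np.ndarray] = None) -> ROCResult:
    """ROC analysis of the HR range against AS/QS labels on the same grid.

    Only valid windows labeled AS or QS enter; AWAKE and UNSCORED windows are
    dropped.  The AUC is the Mann–Whitney probability that a random AS range
    exceeds a random QS range (ties count one half).  The optimal cut point
    maximizes Youden's J = sensitivity + specificity − 1, ties broken toward
    the lower threshold.

    ``labels`` must already be on the window grid (see
    :func:`upsample_annotations`).  ``sample_weight`` optionally weights
    windows in the AUC (e.g. inverse per-subject counts).
    """
    if len(labels) != len(ranges):
        raise ValueError("labels must be aligned with the range-window grid")
    mask = ranges.valid & np.isin(labels.labels, (AS, QS))
    vals = ranges.range_bpm[mask]
    is_as = labels.labels[mask] == AS
    if is_as.all() or (~is_as).all() or vals.size == 0:
        raise ValueError("degenerate labels: need both AS and QS windows")
    w = None if sample_weight is None else np.asarray(sample_weight, dtype=float)[mask]

    auc = float(roc_auc_score(is_as, vals, sample_weight=w))
    thresholds, sens, spec = _roc_points(vals, is_as)
    j = sens + spec - 1.0
    best = int(np.argmax(j))           # argmax returns the first (lowest) threshold on ties
    return ROCResult(thresholds, sens, spec, auc,
                     float(thresholds[best]), float(sens[best]), float(spec[best]))


def select_threshold(meta: SubjectMeta,
                     cfg: ProcessingConfig = DEFAULT_CONFIG) -> float:
    """PMA-stratified cut point: 18 bpm below 37 weeks PMA, else 20 bpm."""
    if meta.pma_weeks is None:
        raise ValueError("PMA is required to select a threshold (no default)")
    if meta.pma_weeks < cfg.pma_split_weeks:
        return cfg.threshold_immature_bpm
    return cfg.threshold_mature_bpm


def classify(ranges: RangeSeries, threshold: float) -> StateAnnotation:
    """Threshold rule on the range grid: range > threshold → AS, else QS.

    The inequality is strict, so a range exactly at the threshold is QS.
    Invalid windows become UNSCORED.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels = np.full(len(ranges), UNSCORED, dtype="U8")
    v = ranges.valid
    labels[v & (ranges.range_bpm > threshold)] = AS
    labels[v & (ranges.range_bpm <= threshold)] = QS
    step = float(ranges.window_starts[1] - ranges.window_starts[0]) \
        if len(ranges) > 1 else 2.0
    return StateAnnotation(ranges.window_starts, labels, epoch_len=step)


def state_fractions(ann: StateAnnotation) -> dict[str, float]:
    """Fraction of scored (non-UNSCORED) epochs per label; sums to 1."""
    scored = ann.labels[ann.labels != UNSCORED]
    if scored.size == 0:
        raise ValueError("no scored epochs")
    labs, counts = np.unique(scored, return_counts=True)
    return {str(l): float(c) / scored.size for l, c in zip(labs, counts)}


class SleepStateClassifier(BaseEstimator, ClassifierMixin):
    """Threshold classifier on the HR-range statistic, sklearn-style.

    ``fit`` either adopts a fixed threshold, derives the PMA-stratified one,
    or — when labeled windows are supplied — calibrates the cut point on the
    empirical ROC at Youden's J.  ``predict`` applies the strict
    ``range > threshold → AS`` rule.

    Parameters
    ----------
    threshold : float, optional
        Fixed cut point in bpm; skips calibration.
    pma_weeks : float, optional
        If given (and ``threshold`` is not), uses the stratified rule
        (18 bpm < 37 weeks, 20 bpm otherwise) and ignores ``y``.
    config : ProcessingConfig, optional

    Attributes
    ----------
    threshold_ : float
        The operating cut point in bpm.
    auc_, sensitivity_, specificity_ : float
        ROC summary at calibration (NaN when the threshold was fixed).
    classes_ : ndarray of shape (2,)
    """

    def __init__(self, threshold: Optional[float] = None,
                 pma_weeks: Optional[float] = None,
                 config: Optional[ProcessingConfig] = None):
        self.threshold = threshold
        self.pma_weeks = pma_weeks
        self.config = config

    def _cfg(self) -> ProcessingConfig:
        return self.config if self.config is not None else DEFAULT_CONFIG

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=False, dtype=float)
        values = X.ravel()
        self.classes_ = np.array([AS, QS])
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
            self.auc_ = self.sensitivity_ = self.specificity_ = float("nan")
            return self
        if self.pma_weeks is not None:
            meta = SubjectMeta("anon", pma_weeks=self.pma_weeks)
            self.threshold_ = select_threshold(meta, self._cfg())
            self.auc_ = self.sensitivity_ = self.specificity_ = float("nan")
            return self
        if y is None:
            raise ValueError("labels are required to calibrate a threshold")
        y = np.asarray(y, dtype="U8")
        keep = np.isin(y, (AS, QS))
        vals, is_as = values[keep], y[keep] == AS
        if is_as.all() or (~is_as).all() or vals.size == 0:
            raise ValueError("degenerate labels: need both AS and QS windows")
        thresholds, sens, spec = _roc_points(vals, is_as)
        j = sens + spec - 1.0
        best = int(np.argmax(j))
        self.threshold_ = float(thresholds[best])
        self.auc_ = float(roc_auc_score(is_as, vals))
        self.sensitivity_ = float(sens[best])
        self.specificity_ = float(spec[best])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "threshold_")
        X = check_array(X, ensure_2d=False, dtype=float)
        return X.ravel() - self.threshold_

    def predict(self, X):
        score = self.decision_function(X)
        return np.where(score > 0, AS, QS)
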