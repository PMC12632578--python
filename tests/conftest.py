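"""Shared fixtures: synthetic recordings are generated at test time, never stored."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import neosleep as ns
from neosleep.synthetic import SyntheticConfig, gen_ecg, gen_hr, gen_states

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

#: single conventional seed for every statistical check in the suite
SUITE_SEED = 12345


@pytest.fixture(scope="session")
def suite_rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def hour_pipeline():
    """One hour of simulated recording pushed through the full HR pipeline.

    Returns a dict with the ground-truth annotation, the true HR series and
    beat times, and the detected/corrected range series with midpoint-paired
    labels.  Session-scoped: several tests reuse the same (seeded) subject.
    """
    cfg = SyntheticConfig(seed=SUITE_SEED)
    rng = np.random.default_rng(SUITE_SEED)
    states = gen_states(cfg, rng)
    hr_true, beat_times, events = gen_hr(states, cfg, rng)
    ecg = gen_ecg(beat_times, fs=cfg.eeg_fs, duration=cfg.total_duration,
                  snr_db=10.0, rng=rng)
    detected = ns.detect_beats(ecg)
    hr = ns.correct_hr(ns.beats_to_hr(detected))
    ranges = ns.compute_range_series(hr)
    labels = ns.window_labels(states, ranges)
    return {
        "cfg": cfg, "states": states, "hr_true": hr_true,
        "beat_times": beat_times, "events": events, "ecg": ecg,
        "detected": detected, "hr": hr, "ranges": ranges, "labels": labels,
    }


def random_hr_series(rng, n_beats=None, jitter=True):
    """A random but physiological HeartRateSeries for property tests."""
    n = n_beats or int(rng.integers(10, 200))
    hr = rng.uniform(90.0, 210.0, size=n)
    dt = 60.0 / hr
    if jitter:
        dt = dt * rng.uniform(0.9, 1.1, size=n)
    times = np.cumsum(dt)
    corrected = rng.random(n) < 0.1
    return ns.HeartRateSeries(times, hr, corrected)
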