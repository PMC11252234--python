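"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from imepmap import EMGTrace, PrestimStats


# --------------------------------------------------------------------------
# independent brute-force detection oracle
#
# A literal, sample-by-sample transcription of the onset/offset rule, kept
# deliberately naive (nested python loops) and separate from the vectorised
# implementation it checks.

def brute_force_detect(samples, fs, stim, mean, sd,
                       search_window_ms=(10.0, 60.0), min_run_ms=5.0):
    thr = mean + sd
    n = len(samples)
    a = stim + int(round(search_window_ms[0] * fs / 1000.0))
    b = min(stim + int(round(search_window_ms[1] * fs / 1000.0)), n - 1)
    n_on = max(int(round(min_run_ms * fs / 1000.0)), 1)
    n_off = n_on + 1
    dt = 1000.0 / fs

    onset = None
    for i in range(a, b + 1):
        if i + n_on > n:
            break
        if all(samples[i + k] > thr for k in range(n_on)):
            onset = i
            break
    if onset is None:
        return None
    offset = b
    for j in range(onset + 1, b + 1):
        if j + n_off > n:
            break
        if all(samples[j + k] < thr for k in range(n_off)):
            offset = j
            break
    return (onset - stim) * dt, (offset - stim) * dt


# --------------------------------------------------------------------------
# trace builders

FS = 2000.0


def make_trace(samples, stim=240, fs=FS, **labels):
    return EMGTrace(np.asarray(samples, dtype=float), fs, stim, **labels)


def step_trace(baseline=10.0, level=20.0, start_ms=20.0, stop_ms=45.0,
               stim=240, n=520, fs=FS):
    """Noise-free rectified-style trace: constant baseline with one square
    excursion after the stimulus."""
    x = np.full(n, baseline)
    i0 = stim + int(round(start_ms * fs / 1000.0))
    i1 = stim + int(round(stop_ms * fs / 1000.0))
    x[i0:i1] = level
    return make_trace(x, stim=stim, fs=fs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240606)


@pytest.fixture(scope="session")
def small_study():
    """2 participants x 3 tasks x 9 sites x 3 trials, cached per session."""
    from imepmap import SyntheticConfig, simulate_dataset
    cfg = SyntheticConfig(n_participants=2, trials_per_site=3, seed=99)
    return simulate_dataset(cfg)


@pytest.fixture
def flat_stats():
    return PrestimStats(10.0, 2.0)
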