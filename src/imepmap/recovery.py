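"""Parameter-recovery experiments: simulated trials with known burst timing
pushed through the default detection chain.

Used by the validation suite and the reproduction script: the generator
plants bursts with fixed onset/duration and the detector must recover them.
"""

from __future__ import annotations

import numpy as np

from .emg import rectify, summarize_site
from .synth import SyntheticConfig, simulate_trial

__all__ = ["timing_recovery"]


def timing_recovery(
    onset_ms: float,
    duration_ms: float,
    gain: float = 4.0,
    n_trials: int = 200,
    trials_per_average: int = 10,
    seed: int = 0,
    cfg: SyntheticConfig | None = None,
) -> dict:
    """Simulate ``n_trials`` sweeps with fixed burst timing and measure the
    mean detected onset and duration.

    Trials are grouped into averages of ``trials_per_average`` (the number of
    pulses delivered per grid site) and each group is detected in the default
    trial-averaged mode; the mean is taken over the detected groups.
    """
    cfg = cfg or SyntheticConfig()
    n_groups = n_trials // trials_per_average
    onsets, durations = [], []
    n_detected = 0
    for g in range(n_groups):
        rects = []
        for k in range(trials_per_average):
            trial_seed = int(np.random.SeedSequence(
                [int(seed) & 0x7FFFFFFF, g, k]).generate_state(1)[0]
                & 0x7FFFFFFF)
            tr, _ = simulate_trial(cfg, gain, trial_seed,
                                   onset_ms=onset_ms,
                                   duration_ms=duration_ms)
            rects.append(rectify(tr))
        s = summarize_site(rects, detection_mode="averaged")
        if s.mean_onset_ms is not None:
            n_detected += 1
            onsets.append(s.mean_onset_ms)
            durations.append(s.mean_duration_ms)
    return {
        "mean_onset_ms": float(np.mean(onsets)) if onsets else float("nan"),
        "mean_duration_ms": (float(np.mean(durations)) if durations
                             else float("nan")),
        "n_groups": n_groups,
        "n_detected": n_detected,
        "n_trials": n_groups * trials_per_average,
    }
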