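"""Rectified-EMG processing: prestimulus statistics, iMEP detection, area.

The detection rule is a threshold-and-run criterion on rectified EMG: the
burst onset is the first post-stimulus sample where the signal exceeds the
prestimulus mean plus one standard deviation for at least 5 ms, and the
offset is the first later sample where it stays below that threshold for more
than 5 ms.  The response size is the relative iMEP area,

    relative_area = area(rectified EMG, onset..offset)
                    / (prestimulus mean * duration) * 100  [%],

i.e. the burst expressed as a percentage of the ongoing background activity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EMGTrace",
    "PrestimStats",
    "IMEPResult",
    "SiteSummary",
    "DegenerateBaselineError",
    "rectify",
    "prestim_stats",
    "pooled_prestim_stats",
    "average_rectified",
    "detect_imep",
    "imep_area",
    "summarize_site",
    "rank_sites",
    "check_background_stability",
]

#: Default post-stimulus search window, ms (start blanks the stimulus
#: artifact, end bounds the physiologically plausible iMEP latency range).
DEFAULT_SEARCH_WINDOW_MS = (10.0, 60.0)
DEFAULT_MIN_RUN_MS = 5.0
DEFAULT_PRESTIM_WINDOW_MS = 100.0


class DegenerateBaselineError(ZeroDivisionError):
    """Raised when the prestimulus mean is zero and the relative area
    (a percentage of baseline) is undefined."""


@dataclass
class EMGTrace:
    """One stimulus-locked EMG sweep.

    Parameters
    ----------
    samples : array of amplitudes in uV.
    sampling_rate : Hz.
    stim_index : sample index of the TMS pulse.
    """

    samples: np.ndarray
    sampling_rate: float
    stim_index: int
    participant: str = ""
    task: str = ""
    site_id: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (0 <= self.stim_index < self.samples.size):
            raise ValueError("stim_index outside the trace")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def time_ms(self) -> np.ndarray:
        """Sample times in ms relative to the stimulus."""
        return (np.arange(self.samples.size) - self.stim_index) * self.dt_ms


@dataclass(frozen=True)
class PrestimStats:
    """Mean and SD of rectified prestimulus EMG (uV)."""

    mean: float
    sd: float
    window_ms: float = DEFAULT_PRESTIM_WINDOW_MS

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("prestimulus mean and SD must be non-negative")

    @property
    def threshold(self) -> float:
        """Detection threshold: mean + 1 SD."""
        return self.mean + self.sd


@dataclass
class IMEPResult:
    """Outcome of iMEP detection on one (possibly trial-averaged) sweep."""

    detected: bool
    onset_ms: float | None = None
    offset_ms: float | None = None
    duration_ms: float | None = None
    area: float | None = None            # uV*ms
    relative_area: float | None = None   # percent of baseline


@dataclass
class SiteSummary:
    """Per-site response summary (the CoG weight a_i and its diagnostics)."""

    site_id: int
    mean_relative_area: float
    mean_onset_ms: float | None
    mean_duration_ms: float | None
    persistence: float
    n_trials: int
    prestim_mean: float = float("nan")
    rank: int | None = None


def rectify(trace: EMGTrace) -> EMGTrace:
    """Full-wave rectification after removing the prestimulus DC offset.

    The DC offset is the raw mean of all samples before the stimulus.
    """
    if trace.stim_index == 0:
        dc = 0.0
    else:
        dc = float(np.mean(trace.samples[:trace.stim_index]))
    out = np.abs(trace.samples - dc)
    return EMGTrace(out, trace.sampling_rate, trace.stim_index,
                    trace.participant, trace.task, trace.site_id)


def _prestim_slice(trace: EMGTrace, window_ms: float) -> slice:
    n = int(round(window_ms * trace.sampling_rate / 1000.0))
    if n < 1:
        raise ValueError("prestimulus window too short")
    start = trace.stim_index - n
    if start < 0:
        raise ValueError(
            f"prestimulus window of {window_ms} ms does not fit before the "
            f"stimulus (only {trace.stim_index} samples available)")
    return slice(start, trace.stim_index)


def prestim_stats(
    rect: EMGTrace, window_ms: float = DEFAULT_PRESTIM_WINDOW_MS,
) -> PrestimStats:
    """Mean and sample SD of the rectified EMG in [stim - window, stim)."""
    seg = rect.samples[_prestim_slice(rect, window_ms)]
    sd = float(np.std(seg, ddof=1)) if seg.size > 1 else 0.0
    return PrestimStats(float(np.mean(seg)), sd, window_ms)


def average_rectified(rects: Sequence[EMGTrace]) -> EMGTrace:
    """Point-wise mean of rectified sweeps (all must share geometry)."""
    if not rects:
        raise ValueError("need at least one trace")
    first = rects[0]
    arr = np.stack([r.samples for r in rects])
    if any(r.sampling_rate != first.sampling_rate
           or r.stim_index != first.stim_index for r in rects):
        raise ValueError("traces must share sampling rate and stimulus index")
    return EMGTrace(arr.mean(axis=0), first.sampling_rate, first.stim_index,
                    first.participant, first.task, first.site_id)


def pooled_prestim_stats(
    rects: Sequence[EMGTrace], window_ms: float = DEFAULT_PRESTIM_WINDOW_MS,
) -> PrestimStats:
    """Baseline statistics pooled over sweeps.

    The mean is the grand mean of the rectified prestimulus samples (equal to
    the prestimulus mean of the trial-averaged sweep); the SD is the sample SD
    of the pooled single-sweep samples.  This is the horizontal-line threshold
    a rater would draw on raw rectified EMG, and is the default baseline when
    detection runs on the trial-averaged waveform: the single-sweep
    variability keeps the threshold calibrated against the raw signal rather
    than against the (much less variable) average.
    """
    if not rects:
        raise ValueError("need at least one trace")
    segs = [r.samples[_prestim_slice(r, window_ms)] for r in rects]
    pooled = np.concatenate(segs)
    sd = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
    return PrestimStats(float(np.mean(pooled)), sd, window_ms)


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    """Centred moving average, edge-padded."""
    if n <= 1:
        return x
    pad = n // 2
    xp = np.pad(x, (pad, n - 1 - pad), mode="edge")
    return np.convolve(xp, np.ones(n) / n, mode="valid")


def detect_imep(
    rect: EMGTrace,
    stats: PrestimStats,
    search_window_ms: tuple[float, float] = DEFAULT_SEARCH_WINDOW_MS,
    min_run_ms: float = DEFAULT_MIN_RUN_MS,
    smooth_ms: float | None = None,
) -> IMEPResult:
    """Apply the threshold-and-run onset/offset rule.

    Onset: first sample within the search window beginning a run of at least
    ``min_run_ms`` consecutive samples strictly above ``stats.mean +
    stats.sd``.  Offset: first later sample beginning a run of more than
    ``min_run_ms`` consecutive samples strictly below the threshold; if no
    such run occurs before the window end, the offset is the window end.
    ``smooth_ms`` optionally applies a centred moving-average envelope before
    thresholding (off by default).
    """
    start_ms, end_ms = search_window_ms
    if start_ms >= end_ms:
        raise ValueError("search window start must precede its end")
    if start_ms < 0:
        raise ValueError("search window must lie after the stimulus")
    fs = rect.sampling_rate
    dt = rect.dt_ms
    x = rect.samples
    if smooth_ms:
        x = _smooth(x, int(round(smooth_ms * fs / 1000.0)))
    n = x.size
    stim = rect.stim_index
    a = stim + int(round(start_ms * fs / 1000.0))
    b = min(stim + int(round(end_ms * fs / 1000.0)), n - 1)
    if a > b:
        return IMEPResult(False)
    n_on = max(int(round(min_run_ms * fs / 1000.0)), 1)
    n_off = n_on + 1   # strictly "more than" min_run_ms
    thr = stats.threshold

    above = x > thr
    # run_above[i] = True iff samples i .. i+n_on-1 are all above threshold
    c = np.concatenate(([0], np.cumsum(above)))
    valid = np.arange(0, n - n_on + 1)
    run_above = (c[valid + n_on] - c[valid]) == n_on

    onset_idx = None
    lo, hi = a, min(b, n - n_on)
    if lo <= hi:
        hits = np.flatnonzero(run_above[lo:hi + 1])
        if hits.size:
            onset_idx = lo + int(hits[0])
    if onset_idx is None:
        return IMEPResult(False)

    below = x < thr
    cb = np.concatenate(([0], np.cumsum(below)))
    offset_idx = b
    lo2, hi2 = onset_idx + 1, min(b, n - n_off)
    if lo2 <= hi2:
        idx = np.arange(lo2, hi2 + 1)
        run_below = (cb[idx + n_off] - cb[idx]) == n_off
        hits = np.flatnonzero(run_below)
        if hits.size:
            offset_idx = lo2 + int(hits[0])

    onset_ms = (onset_idx - stim) * dt
    offset_ms = (offset_idx - stim) * dt
    return IMEPResult(True, onset_ms, offset_ms, offset_ms - onset_ms)


def imep_area(
    rect: EMGTrace, result: IMEPResult, stats: PrestimStats,
) -> float:
    """Relative iMEP area in percent; also fills ``result.area``.

    area = sum of rectified samples in [onset, offset) * dt  (uV*ms);
    relative_area = area / (prestimulus mean * duration) * 100, which reduces
    to the window-mean rectified EMG as a percentage of the baseline mean.
    """
    if not result.detected:
        raise ValueError("cannot compute an area for an undetected iMEP")
    if stats.mean == 0:
        raise DegenerateBaselineError(
            "prestimulus mean is zero; relative area undefined")
    fs = rect.sampling_rate
    stim = rect.stim_index
    i0 = stim + int(round(result.onset_ms * fs / 1000.0))
    i1 = stim + int(round(result.offset_ms * fs / 1000.0))
    dt = rect.dt_ms
    area = float(np.sum(rect.samples[i0:i1]) * dt)
    duration = result.duration_ms
    rel = area / (stats.mean * duration) * 100.0
    result.area = area
    result.relative_area = rel
    return rel


def _mean_or_none(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def summarize_site(
    rects: Sequence[EMGTrace],
    detection_mode: str = "averaged",
    prestim_window_ms: float = DEFAULT_PRESTIM_WINDOW_MS,
    search_window_ms: tuple[float, float] = DEFAULT_SEARCH_WINDOW_MS,
    min_run_ms: float = DEFAULT_MIN_RUN_MS,
    smooth_ms: float | None = None,
    site_id: int | None = None,
) -> SiteSummary:
    """Summarise one stimulation site from its rectified sweeps.

    averaged mode (default): onset/offset/area are measured once on the
    point-wise trial-averaged rectified waveform, against the pooled
    single-sweep baseline threshold.  per_trial mode: each sweep is detected
    and measured on its own, and the site mean is taken over detected trials
    (0 if none).  Persistence is always the per-trial detection fraction.
    """
    if not rects:
        raise ValueError("need at least one trial")
    if detection_mode not in ("averaged", "per_trial"):
        raise ValueError("detection_mode must be 'averaged' or 'per_trial'")
    sid = site_id if site_id is not None else (rects[0].site_id or 0)
    kw = dict(search_window_ms=search_window_ms, min_run_ms=min_run_ms,
              smooth_ms=smooth_ms)

    per_trial: list[IMEPResult] = []
    for r in rects:
        st = prestim_stats(r, prestim_window_ms)
        res = detect_imep(r, st, **kw)
        if res.detected and st.mean > 0:
            imep_area(r, res, st)
        per_trial.append(res)
    detected = [r for r in per_trial if r.detected]
    persistence = len(detected) / len(per_trial)

    if detection_mode == "per_trial":
        areas = [r.relative_area for r in detected if r.relative_area is not None]
        summary = SiteSummary(
            site_id=sid,
            mean_relative_area=float(np.mean(areas)) if areas else 0.0,
            mean_onset_ms=_mean_or_none([r.onset_ms for r in detected]),
            mean_duration_ms=_mean_or_none([r.duration_ms for r in detected]),
            persistence=persistence,
            n_trials=len(rects),
        )
    else:
        avg = average_rectified(rects)
        stats = pooled_prestim_stats(rects, prestim_window_ms)
        res = detect_imep(avg, stats, **kw)
        if res.detected and stats.mean > 0:
            imep_area(avg, res, stats)
        summary = SiteSummary(
            site_id=sid,
            mean_relative_area=(res.relative_area or 0.0) if res.detected else 0.0,
            mean_onset_ms=res.onset_ms if res.detected else None,
            mean_duration_ms=res.duration_ms if res.detected else None,
            persistence=persistence,
            n_trials=len(rects),
        )
    summary.prestim_mean = pooled_prestim_stats(rects, prestim_window_ms).mean
    return summary


def rank_sites(summaries: Iterable[SiteSummary]) -> list[SiteSummary]:
    """Rank sites by mean relative area, 1 = largest; ties by site_id."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one site summary")
    order = sorted(summaries,
                   key=lambda s: (-s.mean_relative_area, s.site_id))
    for rank, s in enumerate(order, start=1):
        s.rank = rank
    return summaries


def check_background_stability(
    prestim_means: dict, rel_tol: float = 0.2,
) -> bool:
    """Warn if background EMG drifts between task conditions.

    ``prestim_means`` maps a task label to its mean prestimulus EMG (uV).
    Emits a warning (never an exclusion) when any task deviates from the
    across-task mean by more than ``rel_tol`` relative.
    """
    vals = np.array(list(prestim_means.values()), dtype=float)
    if vals.size < 2:
        return True
    center = vals.mean()
    if center <= 0:
        return True
    stable = bool(np.all(np.abs(vals - center) / center <= rel_tol))
    if not stable:
        warnings.warn(
            "background EMG differs across tasks by more than "
            f"{rel_tol:.0%} of its mean: "
            + ", ".join(f"{k}={v:.1f}uV" for k, v in prestim_means.items()),
            UserWarning, stacklevel=2)
    return stable
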