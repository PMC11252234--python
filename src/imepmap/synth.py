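"""Synthetic TMS-EMG study generator.

Produces stimulus-locked surface-EMG sweeps over a 3x3 stimulation grid with
known ground truth (burst onset/duration, per-site gain field, true centre of
gravity), so the whole downstream analysis chain can be exercised and its
parameter recovery quantified without any recorded data.

Model
-----
Background EMG during tonic contraction is emulated as stationary band-limited
Gaussian noise (zero-phase Butterworth, 20-1000 Hz by default) scaled to a
target RMS.  An ipsilateral MEP is a multiplicative-envelope burst of
independent band-limited noise added on top of the background, starting
``onset_ms`` after the stimulus and lasting ``duration_ms``; its RMS is
``gain`` times the background RMS.  Spatial tuning of the response follows an
isotropic Gaussian gain field centred on the true CoG.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .emg import EMGTrace

__all__ = [
    "GridSite",
    "GridLayout",
    "SyntheticConfig",
    "TrialTruth",
    "GroundTruth",
    "Study",
    "make_grid",
    "simulate_trial",
    "simulate_dataset",
    "DEFAULT_TASKS",
]

DEFAULT_TASKS = ("iBB", "bBB", "iBB-cAE")

#: Group-mean (mean, SD) burst onset latency per task, ms after the stimulus.
DEFAULT_ONSET_MS = {
    "iBB": (19.8, 2.5),
    "bBB": (20.4, 3.9),
    "iBB-cAE": (20.8, 3.1),
}

#: Group-mean (mean, SD) burst duration per task, ms.
DEFAULT_DURATION_MS = {
    "iBB": (23.9, 15.2),
    "bBB": (21.3, 13.7),
    "iBB-cAE": (25.1, 16.6),
}


@dataclass(frozen=True)
class GridSite:
    """A stimulation target: integer id plus 3-D location in mm."""

    site_id: int
    location: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.location, dtype=float)


@dataclass(frozen=True)
class GridLayout:
    """A planar stimulation lattice embedded in 3-space."""

    sites: tuple[GridSite, ...]
    center: tuple[float, float, float]
    spacing: float
    rows: int
    cols: int

    @property
    def locations(self) -> np.ndarray:
        """(n_sites, 3) array in site_id order."""
        return np.array([s.location for s in self.sites], dtype=float)

    def translated(self, offset: Sequence[float]) -> "GridLayout":
        """Return a copy of the layout shifted rigidly by ``offset`` (mm)."""
        off = np.asarray(offset, dtype=float)
        sites = tuple(
            GridSite(s.site_id, tuple(s.xyz + off)) for s in self.sites
        )
        return GridLayout(
            sites, tuple(np.asarray(self.center) + off), self.spacing,
            self.rows, self.cols,
        )


def make_grid(
    center: Sequence[float] = (0.0, 0.0, 0.0),
    spacing: float = 20.0,
    rows: int = 3,
    cols: int = 3,
) -> GridLayout:
    """Build a rows x cols planar grid centred at ``center``.

    Site ids are assigned row-major (row 0 = most negative y); the default is
    the experimental layout, a 3x3 grid with 2 cm spacing (4 cm x 4 cm total
    extent) centred on the contralateral-MEP hotspot.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    center = np.asarray(center, dtype=float)
    if center.shape != (3,):
        raise ValueError("center must be a 3-vector")
    xs = (np.arange(cols) - (cols - 1) / 2.0) * spacing
    ys = (np.arange(rows) - (rows - 1) / 2.0) * spacing
    sites = []
    sid = 0
    for y in ys:
        for x in xs:
            loc = center + np.array([x, y, 0.0])
            sites.append(GridSite(sid, tuple(loc)))
            sid += 1
    return GridLayout(tuple(sites), tuple(center), float(spacing), rows, cols)


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic mapping study.

    Defaults reproduce the experimental conditions: 20 participants, three
    isometric tasks, 10 pulses at each of 9 grid sites, EMG band-pass
    20-1000 Hz sampled at 2 kHz, 100 ms prestimulus baseline.  ``tuning_center``
    is expressed in the template-grid coordinate frame (the grid is centred on
    the contralateral hotspot at the origin); the default places the true iMEP
    CoG antero-laterally from the hotspot.
    """

    n_participants: int = 20
    tasks: tuple[str, ...] = DEFAULT_TASKS
    trials_per_site: int = 10
    sampling_rate: float = 2000.0
    prestim_duration_ms: float = 120.0
    post_duration_ms: float = 140.0
    background_rms: float = 50.0          # uV; free parameter, see docs
    bandpass: tuple[float, float] = (20.0, 1000.0)
    burst_onset_ms: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ONSET_MS))
    burst_duration_ms: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_MS))
    burst_gain: float = 3.3               # peak of the spatial gain field
    tuning_center: tuple[float, float, float] = (-2.3, 13.25, 0.0)
    tuning_width: float = 15.0            # mm, SD of the Gaussian gain field
    envelope_shape: str = "rectangular"   # or "hanning"
    participant_gain_sd: float = 0.3      # sigma of log-normal gain factor
    hotspot_scatter_mm: float = 5.0       # between-participant grid placement
    artifact_spike: bool = False          # inject a stimulus artifact at t=0
    seed: int = 0

    def validate(self) -> None:
        if self.trials_per_site < 1:
            raise ValueError("trials_per_site must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not self.tasks:
            raise ValueError("task list must be non-empty")
        if self.burst_gain < 0:
            raise ValueError("burst_gain must be non-negative")
        low, high = self.bandpass
        if not (0 < low < high <= self.sampling_rate / 2):
            raise ValueError(
                "bandpass must satisfy 0 < low < high <= Nyquist")
        if self.background_rms <= 0:
            raise ValueError("background_rms must be positive")
        if self.envelope_shape not in ("rectangular", "hanning"):
            raise ValueError("envelope_shape must be rectangular or hanning")
        for task in self.tasks:
            if task not in self.burst_onset_ms or task not in self.burst_duration_ms:
                raise ValueError(f"missing burst timing for task {task!r}")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)

    @property
    def n_samples(self) -> int:
        total_ms = self.prestim_duration_ms + self.post_duration_ms
        return int(round(total_ms * self.sampling_rate / 1000.0))

    @property
    def stim_index(self) -> int:
        return int(round(self.prestim_duration_ms * self.sampling_rate / 1000.0))


@dataclass
class TrialTruth:
    """Generative parameters of one simulated sweep."""

    onset_ms: float
    duration_ms: float
    gain: float
    task: str = ""
    participant: str = ""
    site_id: int | None = None
    trial: int | None = None


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    trials: list[TrialTruth]
    site_gains: dict            # (participant, task, site_id) -> gain
    true_cog: dict              # participant -> 3-vector (mm)
    hotspots: dict              # participant -> 3-vector (mm)
    participant_gain: dict      # participant -> log-normal factor


@dataclass
class Study:
    """A nested container of stimulus-locked sweeps.

    ``trials[(participant, task, site_id)]`` is an (n_trials, n_samples)
    array in uV.  Site coordinates are participant-specific (the grid is
    placed on each participant's hotspot).
    """

    grid: GridLayout
    sampling_rate: float
    stim_index: int
    participants: tuple[str, ...]
    tasks: tuple[str, ...]
    trials: dict
    site_locations: dict        # (participant, site_id) -> 3-vector
    hotspots: dict              # participant -> 3-vector

    def traces(self, participant: str, task: str, site_id: int) -> list[EMGTrace]:
        arr = self.trials[(participant, task, site_id)]
        return [
            EMGTrace(row, self.sampling_rate, self.stim_index,
                     participant=participant, task=task, site_id=site_id)
            for row in arr
        ]


def _band_limit(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase Butterworth band limiting; skips edges at DC/Nyquist."""
    low, high = band
    nyq = fs / 2.0
    if high >= nyq * 0.999:
        sos = signal.butter(4, low, btype="highpass", fs=fs, output="sos")
    else:
        sos = signal.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _seed_from(parts: Sequence[int]) -> int:
    """Derive a child seed (< 2**31) from a tuple of integers."""
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_trial(
    cfg: SyntheticConfig,
    gain: float,
    seed: int,
    task: str | None = None,
    onset_ms: float | None = None,
    duration_ms: float | None = None,
) -> tuple[EMGTrace, TrialTruth]:
    """Simulate one stimulus-locked sweep.

    ``gain`` is the burst RMS as a multiple of the background RMS; gain 0
    yields pure background.  Identical (cfg, gain, seed, timing) arguments
    reproduce the identical sweep bit-for-bit.  When ``onset_ms`` /
    ``duration_ms`` are not given, the task's mean values are used (trial- and
    participant-level variability is applied by :func:`simulate_dataset`).
    """
    cfg.validate()
    if gain < 0:
        raise ValueError("gain must be non-negative")
    task = task if task is not None else cfg.tasks[0]
    if onset_ms is None:
        onset_ms = cfg.burst_onset_ms[task][0]
    if duration_ms is None:
        duration_ms = cfg.burst_duration_ms[task][0]

    fs = cfg.sampling_rate
    n = cfg.n_samples
    stim = cfg.stim_index
    rng = np.random.default_rng(seed)

    bg = _band_limit(rng.standard_normal(n), fs, cfg.bandpass)
    bg *= cfg.background_rms / bg.std()
    x = bg

    if gain > 0:
        burst = _band_limit(rng.standard_normal(n), fs, cfg.bandpass)
        burst *= cfg.background_rms / burst.std()
        i0 = stim + int(round(onset_ms * fs / 1000.0))
        i1 = min(i0 + int(round(duration_ms * fs / 1000.0)), n)
        env = np.zeros(n)
        if i1 > i0:
            if cfg.envelope_shape == "hanning":
                w = np.hanning(i1 - i0)
                # normalise so the burst RMS equals gain * background RMS
                w /= np.sqrt(np.mean(w**2))
            else:
                w = np.ones(i1 - i0)
            env[i0:i1] = w * gain
        x = x + env * burst

    if cfg.artifact_spike:
        # decaying biphasic artifact in the first ~3 ms after the pulse
        k = int(round(3e-3 * fs))
        t = np.arange(k)
        x[stim:stim + k] += (
            20.0 * cfg.background_rms * np.cos(np.pi * t / max(k - 1, 1))
            * np.exp(-t / (k / 2.0))
        )

    trace = EMGTrace(x, fs, stim, task=task)
    truth = TrialTruth(float(onset_ms), float(duration_ms), float(gain), task)
    return trace, truth


def gain_field(
    locations: np.ndarray,
    tuning_center: Sequence[float],
    tuning_width: float,
    peak_gain: float,
) -> np.ndarray:
    """Gaussian spatial tuning: peak_gain * exp(-d^2 / (2 w^2))."""
    d2 = np.sum((np.asarray(locations, float)
                 - np.asarray(tuning_center, float)) ** 2, axis=-1)
    if not np.isfinite(tuning_width) :
        return np.full(d2.shape, float(peak_gain))
    return peak_gain * np.exp(-d2 / (2.0 * tuning_width**2))


def simulate_dataset(
    cfg: SyntheticConfig,
    grid: GridLayout | None = None,
) -> tuple[Study, GroundTruth]:
    """Simulate a full mapping study with per-trial ground truth.

    For each participant, the template grid (and the tuning centre with it) is
    translated by a random hotspot placement, a log-normal factor scales the
    gain field, and task-specific onset/duration are drawn once per
    participant from the configured (mean, SD) and held fixed across that
    participant's trials.  All randomness derives deterministically from
    ``cfg.seed``.
    """
    cfg.validate()
    if grid is None:
        grid = make_grid()

    participants = tuple(f"P{i + 1:02d}" for i in range(cfg.n_participants))
    trials: dict = {}
    site_locations: dict = {}
    hotspots: dict = {}
    truth_trials: list[TrialTruth] = []
    site_gains: dict = {}
    true_cog: dict = {}
    p_gain: dict = {}

    for pi, p in enumerate(participants):
        rng_p = np.random.default_rng(_seed_from([cfg.seed, 1, pi]))
        offset = np.r_[rng_p.normal(0.0, cfg.hotspot_scatter_mm, size=2),
                       rng_p.normal(0.0, cfg.hotspot_scatter_mm / 3.0)]
        pgrid = grid.translated(offset)
        hotspots[p] = np.asarray(pgrid.center)
        center_p = np.asarray(cfg.tuning_center) + offset
        true_cog[p] = center_p
        factor = float(rng_p.lognormal(0.0, cfg.participant_gain_sd))
        p_gain[p] = factor
        gains = gain_field(pgrid.locations, center_p, cfg.tuning_width,
                           cfg.burst_gain) * factor
        for s in pgrid.sites:
            site_locations[(p, s.site_id)] = s.xyz

        for ti, task in enumerate(cfg.tasks):
            mu_on, sd_on = cfg.burst_onset_ms[task]
            mu_du, sd_du = cfg.burst_duration_ms[task]
            onset = float(np.clip(rng_p.normal(mu_on, sd_on), 12.0, 30.0))
            duration = float(np.clip(rng_p.normal(mu_du, sd_du), 8.0, 36.0))
            for s in pgrid.sites:
                g = float(gains[s.site_id])
                site_gains[(p, task, s.site_id)] = g
                arr = np.empty((cfg.trials_per_site, cfg.n_samples))
                for k in range(cfg.trials_per_site):
                    seed_k = _seed_from([cfg.seed, 2, pi, ti, s.site_id, k])
                    tr, tt = simulate_trial(
                        cfg, g, seed_k, task=task,
                        onset_ms=onset, duration_ms=duration)
                    arr[k] = tr.samples
                    tt.participant, tt.site_id, tt.trial = p, s.site_id, k
                    truth_trials.append(tt)
                trials[(p, task, s.site_id)] = arr

    study = Study(
        grid=grid, sampling_rate=cfg.sampling_rate, stim_index=cfg.stim_index,
        participants=participants, tasks=tuple(cfg.tasks), trials=trials,
        site_locations=site_locations, hotspots=hotspots,
    )
    gt = GroundTruth(truth_trials, site_gains, true_cog, hotspots, p_gain)
    return study, gt
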