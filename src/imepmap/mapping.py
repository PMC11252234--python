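"""Amplitude-weighted centre-of-gravity mapping.

The map CoG is the response-weighted mean of stimulation-site locations,

    x_CoG = sum_i a_i x_i / sum_i a_i,

with a_i the (relative) iMEP area at site i and x_i its 3-D location in a
common anatomical space.  Displacements are expressed relative to the
contralateral-MEP hotspot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import GridSite

__all__ = [
    "CoGResult",
    "HotspotRecord",
    "Displacement",
    "NoResponseError",
    "compute_cog",
    "cog_shift",
    "group_cog_table",
]

AXES = ("x", "y", "z")


class NoResponseError(ValueError):
    """All site weights are zero: no CoG can be computed."""


@dataclass
class CoGResult:
    """A weighted-mean map location and the weights that produced it."""

    location: np.ndarray                 # (3,) mm
    weights: np.ndarray                  # the a_i actually used (percent)
    n_nonzero_sites: int
    task: str = ""
    participant: str = ""


@dataclass
class HotspotRecord:
    """Location of the site eliciting the largest contralateral MEP."""

    location: np.ndarray
    muscle: str = "BB"

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        if self.location.shape != (3,) or not np.all(np.isfinite(self.location)):
            raise ValueError("hotspot location must be a finite 3-vector")


@dataclass
class Displacement:
    """Per-axis shift (mm) of a CoG from a reference point."""

    dx: float
    dy: float
    dz: float
    distance: float

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])


def compute_cog(
    sites: Sequence[GridSite],
    weights: Sequence[float],
    task: str = "",
    participant: str = "",
) -> CoGResult:
    """Weighted mean of site locations; weights must be non-negative.

    Invariant to uniform rescaling of all weights.  Raises
    :class:`NoResponseError` when every weight is zero (no detectable
    response anywhere on the grid).
    """
    sites = list(sites)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(sites),):
        raise ValueError("one weight per site is required")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    total = w.sum()
    if total == 0:
        raise NoResponseError("all site weights are zero")
    locs = np.array([s.xyz for s in sites])
    loc = (w[:, None] * locs).sum(axis=0) / total
    return CoGResult(loc, w, int(np.count_nonzero(w)), task, participant)


def cog_shift(imep_cog: CoGResult, hotspot: HotspotRecord) -> Displacement:
    """Displacement of the iMEP CoG from the hotspot, per axis and Euclidean.

    Signs follow the coordinate frame of the inputs (in MNI space, more
    negative x is more lateral on the left hemisphere and larger y is more
    anterior).
    """
    d = np.asarray(imep_cog.location, float) - hotspot.location
    return Displacement(float(d[0]), float(d[1]), float(d[2]),
                        float(np.linalg.norm(d)))


def group_cog_table(
    cogs: Mapping[tuple[str, str], CoGResult],
    tasks: Sequence[str] | None = None,
    ci: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate per-participant CoGs and group means with confidence limits.

    ``cogs`` maps (participant, task) to a CoG.  Returns ``(long, group)``:
    ``long`` has one row per participant x task with x/y/z columns; ``group``
    has one row per task x axis with the mean and the two-sided ``ci``
    t-interval (undefined, NaN, for a single participant).
    """
    if not cogs:
        raise ValueError("no CoGs supplied")
    rows = [
        {"participant": p, "task": t,
         **{ax: float(c.location[i]) for i, ax in enumerate(AXES)}}
        for (p, t), c in cogs.items()
    ]
    long = pd.DataFrame(rows).sort_values(["task", "participant"],
                                          ignore_index=True)
    if tasks is None:
        tasks = list(dict.fromkeys(long["task"]))

    grows = []
    for t in tasks:
        sub = long[long["task"] == t]
        for ax in AXES:
            v = sub[ax].to_numpy()
            mean = float(v.mean())
            if v.size > 1:
                half = sps.t.ppf(0.5 + ci / 2, v.size - 1) * sps.sem(v)
                lo, hi = mean - half, mean + half
            else:
                lo = hi = float("nan")
            grows.append({"task": t, "axis": ax, "n": v.size, "mean": mean,
                          "ci_low": float(lo), "ci_high": float(hi)})
    return long, pd.DataFrame(grows)
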