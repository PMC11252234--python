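"""Reading and writing the canonical on-disk study format.

Layout under a study root::

    sites_<participant>.tsv                site_id, x_mm, y_mm, z_mm
    hotspots.tsv                           participant, x_mm, y_mm, z_mm
    trials/<participant>_<task>_<site>.tsv rows = trials, columns = samples (uV)
    trials/<participant>_<task>_<site>.json  sidecar metadata
    ground_truth.json                      generator truth (synthetic only)

Task labels are slugged in filenames (``iBB-cAE`` -> ``iBB-cAE`` is safe as
is); sidecars carry the unslugged label.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emg import SiteSummary
from .mapping import CoGResult
from .synth import GridLayout, GridSite, GroundTruth, Study

__all__ = [
    "write_study", "read_study",
    "write_summary_table", "read_summary_table",
    "write_cog_json", "write_group_cog_table",
    "write_comparison_json", "write_json",
]

_SIDECAR_KEYS = ("sampling_rate_hz", "stim_sample_index", "prestim_ms",
                 "participant", "task", "site_id")


def write_json(obj, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_study(study: Study, root: Path | str,
                ground_truth: GroundTruth | None = None) -> Path:
    root = Path(root)
    tdir = root / "trials"
    tdir.mkdir(parents=True, exist_ok=True)

    for p in study.participants:
        rows = [{"site_id": sid, "x_mm": loc[0], "y_mm": loc[1], "z_mm": loc[2]}
                for (pp, sid), loc in sorted(study.site_locations.items())
                if pp == p]
        pd.DataFrame(rows).to_csv(root / f"sites_{p}.tsv", sep="\t",
                                  index=False)
    pd.DataFrame(
        [{"participant": p, "x_mm": h[0], "y_mm": h[1], "z_mm": h[2]}
         for p, h in study.hotspots.items()]
    ).to_csv(root / "hotspots.tsv", sep="\t", index=False)

    prestim_ms = study.stim_index / study.sampling_rate * 1000.0
    for (p, task, sid), arr in study.trials.items():
        stem = f"{p}_{task}_{sid}"
        np.savetxt(tdir / f"{stem}.tsv", arr, delimiter="\t", fmt="%.4f")
        write_json(
            {"sampling_rate_hz": study.sampling_rate,
             "stim_sample_index": study.stim_index,
             "prestim_ms": prestim_ms,
             "participant": p, "task": task, "site_id": sid},
            tdir / f"{stem}.json")

    write_json(
        {"participants": list(study.participants),
         "tasks": list(study.tasks),
         "grid": {"center": list(study.grid.center),
                  "spacing": study.grid.spacing,
                  "rows": study.grid.rows, "cols": study.grid.cols}},
        root / "study.json")

    if ground_truth is not None:
        write_json(
            {"true_cog": {p: list(v) for p, v in ground_truth.true_cog.items()},
             "hotspots": {p: list(v) for p, v in ground_truth.hotspots.items()},
             "participant_gain": ground_truth.participant_gain,
             "site_gains": {f"{p}|{t}|{s}": g for (p, t, s), g
                            in ground_truth.site_gains.items()},
             "trials": [t.__dict__ for t in ground_truth.trials]},
            root / "ground_truth.json")
    return root


def read_study(root: Path | str) -> Study:
    root = Path(root)
    meta = json.loads((root / "study.json").read_text())
    g = meta["grid"]
    from .synth import make_grid
    grid = make_grid(g["center"], g["spacing"], g["rows"], g["cols"])

    hs = pd.read_csv(root / "hotspots.tsv", sep="\t")
    hotspots = {r.participant: np.array([r.x_mm, r.y_mm, r.z_mm])
                for r in hs.itertuples()}

    site_locations = {}
    for p in meta["participants"]:
        df = pd.read_csv(root / f"sites_{p}.tsv", sep="\t")
        for r in df.itertuples():
            site_locations[(p, int(r.site_id))] = np.array(
                [r.x_mm, r.y_mm, r.z_mm])

    trials = {}
    fs = stim = None
    for sidecar in sorted((root / "trials").glob("*.json")):
        side = json.loads(sidecar.read_text())
        missing = [k for k in _SIDECAR_KEYS if k not in side]
        if missing:
            raise ValueError(f"{sidecar.name}: sidecar missing {missing}")
        arr = np.loadtxt(sidecar.with_suffix(".tsv"), delimiter="\t", ndmin=2)
        key = (side["participant"], side["task"], int(side["site_id"]))
        trials[key] = arr
        fs, stim = side["sampling_rate_hz"], int(side["stim_sample_index"])
    if fs is None:
        raise ValueError(f"no trial files found under {root / 'trials'}")

    return Study(grid=grid, sampling_rate=fs, stim_index=stim,
                 participants=tuple(meta["participants"]),
                 tasks=tuple(meta["tasks"]), trials=trials,
                 site_locations=site_locations, hotspots=hotspots)


_SUMMARY_COLS = ["participant", "task", "site_id", "mean_relative_area",
                 "mean_onset_ms", "mean_duration_ms", "persistence",
                 "prestim_mean", "rank"]


def summaries_to_frame(summaries: dict) -> pd.DataFrame:
    """``summaries[(participant, task)] -> list[SiteSummary]`` to long TSV form."""
    rows = []
    for (p, task), ss in summaries.items():
        for s in ss:
            rows.append({
                "participant": p, "task": task, "site_id": s.site_id,
                "mean_relative_area": s.mean_relative_area,
                "mean_onset_ms": s.mean_onset_ms,
                "mean_duration_ms": s.mean_duration_ms,
                "persistence": s.persistence,
                "prestim_mean": s.prestim_mean,
                "rank": s.rank,
            })
    return pd.DataFrame(rows, columns=_SUMMARY_COLS)


def _write_tsv(df: pd.DataFrame, path: Path | str,
               meta: dict | None = None) -> Path:
    """TSV with optional '# key: value' provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def write_summary_table(summaries: dict, path: Path | str,
                        meta: dict | None = None) -> Path:
    return _write_tsv(summaries_to_frame(summaries), path, meta)


def read_summary_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_cog_json(cogs: dict, path: Path | str,
                   meta: dict | None = None) -> Path:
    """``cogs[(participant, task)] -> CoGResult`` to one JSON file."""
    payload = {
        **(meta or {}),
        "cogs": [
            {"participant": p, "task": t, "location": list(c.location),
             "weights": list(np.asarray(c.weights, float)),
             "n_nonzero_sites": c.n_nonzero_sites}
            for (p, t), c in sorted(cogs.items())
        ],
    }
    return write_json(payload, path)


def write_group_cog_table(group_df: pd.DataFrame, path: Path | str,
                          meta: dict | None = None) -> Path:
    return _write_tsv(group_df, path, meta)


def write_comparison_json(results_by_axis: dict, path: Path | str,
                          meta: dict | None = None) -> Path:
    """Per-axis BestResults to JSON (posterior summaries, accuracy, tier)."""
    payload = {**(meta or {}),
               **{ax: res.to_dict() for ax, res in results_by_axis.items()}}
    return write_json(payload, path)
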