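"""End-to-end orchestration: simulate -> detect -> map -> compare -> task model.

Each stage is callable on its own (the CLI subcommands map onto them) and
:func:`run_pipeline` chains them, writing all tabular outputs and a single
JSON run report that embeds the seed, a hash of the configuration, and the
package version, so a run is reproducible from its report alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .emg import rectify, summarize_site, rank_sites, check_background_stability
from .inference import MCMCConfig, compare_centroids_by_axis, levene_test
from .io import (_write_tsv, write_study, read_study, write_summary_table,
                 summaries_to_frame, write_cog_json, write_group_cog_table,
                 write_comparison_json, write_json)
from .mapping import (AXES, CoGResult, HotspotRecord, NoResponseError,
                      compute_cog, cog_shift, group_cog_table)
from .synth import GridSite, Study, SyntheticConfig, simulate_dataset
from .taskmodel import TaskAreaModel, TaskAreaRecord, summarize_task_areas

log = logging.getLogger("imepmap")

__all__ = ["DetectionParams", "RunConfig", "run_pipeline",
           "detect_study", "map_study", "compare_study", "task_records"]


@dataclass(frozen=True)
class DetectionParams:
    detection_mode: str = "averaged"
    search_window_ms: tuple[float, float] = (10.0, 60.0)
    min_run_ms: float = 5.0
    prestim_window_ms: float = 100.0
    smooth_ms: float | None = None


@dataclass
class RunConfig:
    """Everything a pipeline run needs; JSON-serialisable."""

    out_dir: str = "imepmap_out"
    input_dir: str | None = None            # read an existing study instead
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    seed: int = 0
    log_level: str = "INFO"
    write_trials: bool = False              # trial TSVs are bulky; opt in

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = dict(d["synthetic"])
            for k in ("tasks",):
                if k in syn:
                    syn[k] = tuple(syn[k])
            for k in ("bandpass", "tuning_center"):
                if k in syn:
                    syn[k] = tuple(syn[k])
            for k in ("burst_onset_ms", "burst_duration_ms"):
                if k in syn:
                    syn[k] = {t: tuple(v) for t, v in syn[k].items()}
            d["synthetic"] = SyntheticConfig(**syn)
        if d.get("detection") is not None:
            det = dict(d["detection"])
            if "search_window_ms" in det:
                det["search_window_ms"] = tuple(det["search_window_ms"])
            d["detection"] = DetectionParams(**det)
        if d.get("mcmc") is not None:
            d["mcmc"] = MCMCConfig(**d["mcmc"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# stages

def detect_study(study: Study, det: DetectionParams | None = None) -> dict:
    """Run detection for every participant/task/site.

    Returns ``{(participant, task): [SiteSummary, ...]}`` with ranks filled
    per participant x task.
    """
    det = det or DetectionParams()
    out = {}
    for p in study.participants:
        for task in study.tasks:
            ss = []
            for s in study.grid.sites:
                rects = [rectify(tr) for tr in study.traces(p, task, s.site_id)]
                ss.append(summarize_site(
                    rects, detection_mode=det.detection_mode,
                    prestim_window_ms=det.prestim_window_ms,
                    search_window_ms=det.search_window_ms,
                    min_run_ms=det.min_run_ms, smooth_ms=det.smooth_ms,
                    site_id=s.site_id))
            rank_sites(ss)
            out[(p, task)] = ss
    # data-quality check: background EMG stability across tasks
    for p in study.participants:
        means = {task: float(np.mean([s.prestim_mean
                                      for s in out[(p, task)]]))
                 for task in study.tasks}
        check_background_stability(means)
    return out


def map_study(study: Study, summaries: dict) -> tuple[dict, dict]:
    """Compute per-participant/task CoGs from site summaries.

    Returns ``(cogs, failures)`` where ``failures[(p, task)]`` is a reason
    string for combinations with no detectable response anywhere.
    """
    cogs, failures = {}, {}
    for (p, task), ss in summaries.items():
        sites = [GridSite(s.site_id, tuple(study.site_locations[(p, s.site_id)]))
                 for s in ss]
        weights = [s.mean_relative_area for s in ss]
        try:
            cogs[(p, task)] = compute_cog(sites, weights, task=task,
                                          participant=p)
        except NoResponseError as exc:
            failures[(p, task)] = str(exc)
    return cogs, failures


def compare_study(
    cogs: dict, hotspots: dict, tasks, mcmc: MCMCConfig,
) -> dict:
    """Per-task, per-axis Bayesian comparison of CoGs vs hotspots."""
    out = {}
    for ti, task in enumerate(tasks):
        per_p = {p: c.location for (p, t), c in cogs.items() if t == task}
        if len(per_p) < 2:
            out[task] = None
            continue
        hs = {p: hotspots[p] for p in per_p}
        cfg_t = dataclasses.replace(
            mcmc, seed=int(np.random.SeedSequence(
                [int(mcmc.seed) & 0x7FFFFFFF, 7 + ti]).generate_state(1)[0]
                & 0x7FFFFFFF))
        out[task] = compare_centroids_by_axis(per_p, hs, cfg_t)
    return out


def _hotspot_site_id(study: Study, participant: str) -> int:
    hs = study.hotspots[participant]
    sids = [s.site_id for s in study.grid.sites]
    d = [np.linalg.norm(study.site_locations[(participant, sid)] - hs)
         for sid in sids]
    return sids[int(np.argmin(d))]


def task_records(study: Study, summaries: dict) -> list[TaskAreaRecord]:
    """Build the LMM input: areas at the max site and at the hotspot site."""
    records = []
    for (p, task), ss in summaries.items():
        by_id = {s.site_id: s for s in ss}
        max_site = next(s for s in ss if s.rank == 1)
        hot = by_id[_hotspot_site_id(study, p)]
        for role, s in (("max_site", max_site), ("hotspot_site", hot)):
            records.append(TaskAreaRecord(
                participant=p, task=task, site_role=role,
                relative_area=s.mean_relative_area,
                background_emg=s.prestim_mean))
    return records


# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write outputs + a JSON run report.

    Returns the report as a dict (also written to ``<out>/report.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "tasks": {},
        "incomplete": False,
    }
    meta = {"seed": config.seed, "config_hash": report["config_hash"]}

    def timed(name):
        t0 = time.perf_counter()

        def done(**counts):
            report["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **counts}
            log.info("stage %s done in %.2fs %s", name,
                     time.perf_counter() - t0, counts)
        return done

    # -- stage 1: data ----------------------------------------------------
    done = timed("data")
    if config.input_dir is not None:
        study = read_study(config.input_dir)
        gt = None
    elif config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        study, gt = simulate_dataset(syn)
        if config.write_trials:
            write_study(study, out / "study", gt)
    else:
        raise ValueError("config must request synthetic data or point at "
                         "an input directory")
    n_traces = sum(a.shape[0] for a in study.trials.values())
    done(participants=len(study.participants), traces=n_traces)

    # -- stage 2: detection ----------------------------------------------
    done = timed("detect")
    summaries = detect_study(study, config.detection)
    write_summary_table(summaries, out / "summary.tsv", meta=meta)
    sdf = summaries_to_frame(summaries)
    done(site_summaries=len(sdf),
         detected=int((sdf["mean_relative_area"] > 0).sum()))

    # -- stage 3: mapping -------------------------------------------------
    done = timed("map")
    cogs, failures = map_study(study, summaries)
    if cogs:
        write_cog_json(cogs, out / "cogs.json", meta=meta)
        long_df, group_df = group_cog_table(cogs, tasks=study.tasks)
        write_group_cog_table(group_df, out / "group_cog.tsv", meta=meta)
    else:
        long_df = group_df = None
    done(cogs=len(cogs), no_response=len(failures))

    hotspot_records = {p: HotspotRecord(h) for p, h in study.hotspots.items()}
    for task in study.tasks:
        task_cogs = {p: c for (p, t), c in cogs.items() if t == task}
        entry: dict = {}
        if not task_cogs:
            entry["status"] = "no_response"
            report["tasks"][task] = entry
            continue
        entry["status"] = "ok"
        entry["n_participants"] = len(task_cogs)
        gm = np.mean([c.location for c in task_cogs.values()], axis=0)
        entry["group_cog"] = [round(float(v), 3) for v in gm]
        shifts = [cog_shift(c, hotspot_records[p]).vector
                  for p, c in task_cogs.items()]
        entry["mean_shift_mm"] = [round(float(v), 3)
                                  for v in np.mean(shifts, axis=0)]
        report["tasks"][task] = entry

    # -- stage 4: Bayesian comparison ------------------------------------
    done = timed("compare")
    mcmc = dataclasses.replace(config.mcmc, seed=config.seed)
    comparisons = compare_study(cogs, study.hotspots, study.tasks, mcmc)
    n_cmp = 0
    for task, res in comparisons.items():
        if res is None:
            continue
        write_comparison_json(res, out / f"comparison_{task}.json",
                              meta=meta)
        report["tasks"][task]["comparison"] = {
            ax: r.to_dict() for ax, r in res.items()}
        n_cmp += len(res)
    done(comparisons=n_cmp)

    # -- stage 5: task model ----------------------------------------------
    done = timed("taskmodel")
    records = task_records(study, summaries)
    report["task_model"] = {}
    if records:
        table = summarize_task_areas(records)
        _write_tsv(table, out / "task_areas.tsv", meta=meta)
        report["task_areas"] = table.to_dict(orient="records")
        # heteroscedasticity check on max-site areas across tasks
        groups = [
            [r.relative_area for r in records
             if r.site_role == "max_site" and r.task == task]
            for task in study.tasks]
        flat = [v for g in groups for v in g]
        if all(len(g) >= 2 for g in groups) and np.std(flat) > 0:
            w, p = levene_test(groups)
            report["levene"] = {"W": round(w, 4), "p": round(p, 4)}
        for role in ("max_site", "hotspot_site"):
            try:
                res = TaskAreaModel.from_records(records, role).fit()
                report["task_model"][role] = res.to_dict()
            except ValueError as exc:
                report["task_model"][role] = {"status": f"skipped: {exc}"}
    else:
        report["incomplete"] = True
    done(records=len(records))

    if failures or any(v.get("status") == "no_response"
                       for v in report["tasks"].values()):
        report["incomplete"] = bool(failures)
        report["no_response"] = [f"{p}/{t}" for (p, t) in failures]

    write_json(report, out / "report.json")
    return report
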