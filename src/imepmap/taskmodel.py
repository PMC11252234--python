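"""Task modulation of iMEP area: linear mixed-effects analysis.

Relative iMEP area is modelled with TASK as a categorical fixed effect, a
random intercept per participant, and background EMG as a fixed covariate
(a continuous measurement cannot serve as a grouping factor; a random slope
on background EMG is available behind a flag).  The omnibus TASK test is a
likelihood-ratio test between maximum-likelihood fits with and without TASK;
a Wald chi-square (and its F form) from the REML fit is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "TaskAreaRecord",
    "TaskAreaModel",
    "TaskModelResults",
    "fit_task_lmm",
    "summarize_task_areas",
]

SITE_ROLES = ("max_site", "hotspot_site")


@dataclass(frozen=True)
class TaskAreaRecord:
    """One participant x task x site-role response-size observation."""

    participant: str
    task: str
    site_role: str
    relative_area: float
    background_emg: float = float("nan")

    def __post_init__(self) -> None:
        if self.relative_area < 0:
            raise ValueError("relative_area must be non-negative")
        if self.site_role not in SITE_ROLES:
            raise ValueError(f"site_role must be one of {SITE_ROLES}")


def _records_frame(records: Iterable[TaskAreaRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class TaskModelResults:
    """Omnibus TASK test and fitted effects.

    ``statistic``/``p_value`` are the likelihood-ratio chi-square test (the
    primary test); ``wald_f``/``p_wald`` give the Wald F on the TASK terms
    from the REML fit (no small-sample df correction).
    """

    statistic: float
    df: int
    p_value: float
    method: str
    wald_f: float | None
    p_wald: float | None
    params: pd.Series | None
    n_participants: int
    n_obs: int
    converged: bool
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def summary(self) -> str:
        lines = [
            "Task-modulation mixed model",
            f"  observations: {self.n_obs} from {self.n_participants} participants",
            f"  omnibus TASK ({self.method}): chi2({self.df}) = "
            f"{self.statistic:.3f}, p = {self.p_value:.4f}",
        ]
        if self.wald_f is not None:
            lines.append(
                f"  Wald: F({self.df}, inf) = {self.wald_f:.3f}, "
                f"p = {self.p_wald:.4f}")
        if self.params is not None:
            lines.append("  fixed effects:")
            for k, v in self.params.items():
                lines.append(f"    {k:<28s} {v:10.3f}")
        if self.note:
            lines.append(f"  note: {self.note}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "df": self.df,
            "p_value": self.p_value, "method": self.method,
            "wald_f": self.wald_f, "p_wald": self.p_wald,
            "n_participants": self.n_participants, "n_obs": self.n_obs,
            "converged": self.converged, "note": self.note,
        }


class TaskAreaModel:
    """Mixed model of relative iMEP area with TASK as fixed effect.

    Build from a long DataFrame (columns ``participant``, ``task``,
    ``relative_area`` and optionally ``background_emg``) or from
    :class:`TaskAreaRecord` rows via :meth:`from_records`.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"participant", "task", "relative_area"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = data.copy()
        if df["task"].nunique() < 2:
            raise ValueError("need at least two task levels")
        if df["participant"].nunique() < 2:
            raise ValueError("need at least two participants")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[TaskAreaRecord], site_role: str | None = None,
    ) -> "TaskAreaModel":
        df = _records_frame(records)
        if site_role is not None:
            df = df[df["site_role"] == site_role]
        return cls(df)

    def fit(
        self,
        include_background: bool = True,
        background_random_slope: bool = False,
        compute_wald: bool = True,
    ) -> TaskModelResults:
        """Fit and test the TASK effect.

        ``compute_wald=False`` skips the REML refit (useful in simulation
        loops where only the LRT p-value matters).  Returns a failed-status
        result (``converged=False``) rather than raising if the optimiser
        does not converge.
        """
        df = self.data.copy()
        has_bg = (include_background and "background_emg" in df.columns
                  and df["background_emg"].notna().all()
                  and df["background_emg"].nunique() > 1)
        n_p = df["participant"].nunique()
        n_tasks = df["task"].nunique()
        dof = n_tasks - 1

        if float(df["relative_area"].std(ddof=0)) == 0.0:
            # all responses identical: the TASK effect is exactly null
            return TaskModelResults(
                0.0, dof, 1.0, "lrt", 0.0, 1.0, None, n_p, len(df), True,
                note="degenerate response (zero variance)")

        base = "relative_area ~ "
        cov = " + background_emg" if has_bg else ""
        f_full = base + "C(task)" + cov
        f_null = base + ("background_emg" if has_bg else "1")
        re_formula = "~background_emg" if (background_random_slope and has_bg) \
            else None
        kw = dict(groups=df["participant"], re_formula=re_formula)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                full_ml = smf.mixedlm(f_full, df, **kw).fit(reml=False)
                null_ml = smf.mixedlm(f_null, df, **kw).fit(reml=False)
                full_reml = (smf.mixedlm(f_full, df, **kw).fit(reml=True)
                             if compute_wald else None)
            except Exception as exc:   # singular fits etc.
                return TaskModelResults(
                    float("nan"), dof, float("nan"), "lrt", None, None, None,
                    n_p, len(df), False, note=f"fit failed: {exc}")

        converged = bool(getattr(full_ml, "converged", True)
                         and getattr(null_ml, "converged", True))
        lr = max(2.0 * (full_ml.llf - null_ml.llf), 0.0)
        p = float(sps.chi2.sf(lr, dof))

        wald_f = p_wald = None
        task_terms = ([] if full_reml is None else
                      [n for n in full_reml.fe_params.index
                       if n.startswith("C(task)")])
        if task_terms:
            try:
                k_total = len(full_reml.params)
                R = np.zeros((len(task_terms), k_total))
                names = list(full_reml.model.exog_names)
                for i, t in enumerate(task_terms):
                    R[i, names.index(t)] = 1.0
                wt = full_reml.wald_test(R, scalar=True)
                chi2 = float(np.squeeze(wt.statistic))
                wald_f = chi2 / dof
                p_wald = float(sps.chi2.sf(chi2, dof))
            except Exception:
                pass

        return TaskModelResults(
            float(lr), dof, p, "lrt", wald_f, p_wald,
            None if full_reml is None else full_reml.fe_params,
            n_p, len(df), converged)


def fit_task_lmm(
    records: Iterable[TaskAreaRecord],
    site_role: str = "max_site",
    **fit_kw,
) -> TaskModelResults:
    """Convenience wrapper: build the model for one site role and fit it."""
    return TaskAreaModel.from_records(records, site_role).fit(**fit_kw)


def summarize_task_areas(
    records: Iterable[TaskAreaRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-task mean +/- sample SD of relative area for each site role.

    With a single observation the SD is reported as 0 with
    ``sd_undefined=True``.
    """
    df = records if isinstance(records, pd.DataFrame) else _records_frame(records)
    if df.empty:
        raise ValueError("no records supplied")
    rows = []
    for (role, task), sub in df.groupby(["site_role", "task"], sort=False):
        v = sub["relative_area"].to_numpy(dtype=float)
        rows.append({
            "site_role": role, "task": task, "n": v.size,
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "sd_undefined": v.size < 2,
        })
    return pd.DataFrame(rows)
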