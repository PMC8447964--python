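"""Dose-response statistics for the self-paced cued reaching task.

Each session contributes a total attempted-reach count (task engagement)
and a premature-reach count (impulsivity). Drug-naive sessions (dose 0)
are pooled and summarized with a 90% t-interval; harmaline-dose sessions
are summarized per dose. The dose-response statistic is the Pearson
correlation between dose and the per-dose mean of a metric, with the
two-sided p-value from t = r sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of
freedom. With four dose levels plus the pooled drug-naive point the
correlation has n = 5 points (df = 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .types import DoseResponse, TaskSession

__all__ = [
    "TaskSummary",
    "summarize_sessions",
    "pearson_p_value",
    "dose_response",
    "dose_response_from_sessions",
    "read_task_log",
    "write_task_log",
]


@dataclass
class TaskSummary:
    """Per-dose means plus the pooled drug-naive summary."""

    per_dose: pd.DataFrame  # dose, n_sessions, mean_attempted, mean_premature_frac
    naive_mean_attempted: float | None
    naive_attempted_ci90: tuple[float, float] | None
    naive_mean_premature_frac: float | None
    naive_premature_ci90: tuple[float, float] | None


def _t_interval(values: np.ndarray, level: float = 0.90):
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    if values.size < 2:
        return m, (m, m)
    se = values.std(ddof=1) / np.sqrt(values.size)
    half = stats.t.ppf(0.5 + level / 2, values.size - 1) * se
    return m, (m - half, m + half)


def summarize_sessions(sessions: list[TaskSession]) -> TaskSummary:
    """Mean attempted reaches and premature fraction per dose.

    Drug-naive sessions (dose 0) are pooled with 90% t-intervals.
    Sessions with zero attempted reaches have an undefined premature
    fraction and are excluded from that metric with a warning.
    """
    if not sessions:
        raise InputError("no task sessions supplied")
    rows = []
    for s in sessions:
        frac = s.premature_fraction
        if frac is None:
            warnings.warn(
                f"session at dose {s.dose_mg_per_kg} mg/kg has zero "
                "attempted reaches; premature fraction undefined",
                stacklevel=2)
        rows.append((s.dose_mg_per_kg, s.attempted_reaches, frac))
    df = pd.DataFrame(rows, columns=["dose", "attempted", "premature_frac"])
    per_dose = (
        df[df["dose"] > 0]
        .groupby("dose")
        .agg(n_sessions=("attempted", "size"),
             mean_attempted=("attempted", "mean"),
             mean_premature_frac=("premature_frac", "mean"))
        .reset_index()
    )
    naive = df[df["dose"] == 0]
    if len(naive):
        mean_att, ci_att = _t_interval(naive["attempted"].to_numpy())
        fr = naive["premature_frac"].dropna().to_numpy()
        mean_fr, ci_fr = _t_interval(fr) if len(fr) else (None, None)
    else:
        mean_att = ci_att = mean_fr = ci_fr = None
    return TaskSummary(
        per_dose=per_dose,
        naive_mean_attempted=mean_att,
        naive_attempted_ci90=ci_att,
        naive_mean_premature_frac=mean_fr,
        naive_premature_ci90=ci_fr,
    )


def pearson_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the exact t transform (df = n-2)."""
    if not -1 <= r <= 1:
        raise InputError("correlation must lie in [-1, 1]")
    if n < 3:
        raise InputError("need at least 3 points")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))


def dose_response(
    doses: np.ndarray, means: np.ndarray, metric: str = ""
) -> DoseResponse:
    """Pearson correlation between dose and a per-dose metric mean."""
    doses = np.asarray(doses, dtype=float)
    means = np.asarray(means, dtype=float)
    if len(np.unique(doses)) < 3:
        raise InputError("dose-response needs >= 3 distinct dose levels")
    if np.ptp(means) == 0 or np.ptp(doses) == 0:
        raise InputError(
            f"metric {metric!r} has zero variance; correlation undefined")
    r = float(np.corrcoef(doses, means)[0, 1])
    return DoseResponse(
        metric=metric,
        doses=doses,
        means=means,
        pearson_r=r,
        p_value=pearson_p_value(r, len(doses)),
    )


def dose_response_from_sessions(
    sessions: list[TaskSession],
    metric: str = "attempted",
    include_naive: bool = True,
) -> DoseResponse:
    """Dose-response over per-dose means, optionally with the pooled
    drug-naive sessions as the dose-0 point.

    ``metric`` is "attempted" (mean attempted reaches) or "premature"
    (mean within-session premature fraction).
    """
    if metric not in ("attempted", "premature"):
        raise InputError(f"unknown metric {metric!r}")
    summ = summarize_sessions(sessions)
    col = "mean_attempted" if metric == "attempted" else "mean_premature_frac"
    doses = summ.per_dose["dose"].to_list()
    means = summ.per_dose[col].to_list()
    if include_naive and summ.naive_mean_attempted is not None:
        naive_val = (summ.naive_mean_attempted if metric == "attempted"
                     else summ.naive_mean_premature_frac)
        doses = [0.0] + doses
        means = [naive_val] + means
    return dose_response(np.array(doses), np.array(means), metric=metric)


def read_task_log(path) -> list[TaskSession]:
    """Read a task log CSV (dose, minutes, attempted, premature per row)."""
    df = pd.read_csv(path)
    required = {"dose_mg_per_kg", "session_minutes", "attempted_reaches",
                "premature_reaches"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"task log missing columns: {sorted(missing)}")
    return [
        TaskSession(
            dose_mg_per_kg=float(r.dose_mg_per_kg),
            session_minutes=float(r.session_minutes),
            attempted_reaches=int(r.attempted_reaches),
            premature_reaches=int(r.premature_reaches),
        )
        for r in df.itertuples()
    ]


def write_task_log(sessions: list[TaskSession], path) -> None:
    """Write task sessions as a one-row-per-session CSV."""
    pd.DataFrame(
        [(s.dose_mg_per_kg, s.session_minutes, s.attempted_reaches,
          s.premature_reaches) for s in sessions],
        columns=["dose_mg_per_kg", "session_minutes", "attempted_reaches",
                 "premature_reaches"],
    ).to_csv(path, index=False)
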