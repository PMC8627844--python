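"""Data-quality checks producing the analytic sample.

Four per-respondent criteria mirror routine cTTO quality control:

* wheelchair-example timer: at least 3 minutes (180 s) explaining the task;
* cTTO-task timer: at least 10 minutes (600 s) across all 20 tasks;
* the worst state 55555 received the (weakly) lowest value;
* severe inconsistency: some logically better state valued 0.5 or more
  below a state it dominates.

Only severe inconsistency excludes a respondent from the analytic sample;
the timing and worst-state criteria are report-only. Interviewer-effect
summaries compare the proportion of worse-than-dead responses, the
proportions exactly at -1, 0 and 1, and the value distribution deciles
between interviewers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import grid_index
from .states import dominates

logger = logging.getLogger(__name__)

WHEELCHAIR_MIN_SECONDS = 180.0
CTTO_MIN_SECONDS = 600.0
SEVERE_INCONSISTENCY_GAP = 0.5


@dataclass(frozen=True)
class QCReport:
    """Per-respondent flags, per-interviewer summaries and the analytic ids."""

    respondent_flags: pd.DataFrame  # indexed by respondent_id
    interviewer_summary: pd.DataFrame
    analytic_ids: tuple[int, ...]

    @property
    def n_flagged(self) -> int:
        return int(self.respondent_flags["severe_inconsistency"].sum())

    def write(self, flags_path: str | Path, interviewers_path: str | Path) -> None:
        self.respondent_flags.to_csv(flags_path)
        self.interviewer_summary.to_csv(interviewers_path)


def flag_compliance(group: pd.DataFrame) -> dict[str, bool]:
    """Timing-compliance flags for one respondent's responses."""
    wheelchair = group["wheelchair_seconds"]
    tasks = group["task_seconds"]
    if wheelchair.isna().any() or tasks.isna().any():
        logger.warning("missing timings for respondent; flagging as violation")
        return {"wheelchair_time_violation": True, "ctto_time_violation": True}
    return {
        "wheelchair_time_violation": bool(wheelchair.iloc[0] < WHEELCHAIR_MIN_SECONDS),
        "ctto_time_violation": bool(tasks.sum() < CTTO_MIN_SECONDS),
    }


def flag_severe_inconsistency(
    group: pd.DataFrame,
) -> tuple[bool, list[tuple[str, str]]]:
    """Severe-inconsistency check for one respondent.

    Violation: a dominating pair (a better than b) with
    ctto(a) <= ctto(b) - 0.5; the 0.5 boundary itself violates. Comparison
    is done on integer grid coordinates, so it is exact.
    Returns the flag and all offending (better, worse) pairs.
    """
    states = [str(s) for s in group["state"]]
    if len(set(states)) != len(states):
        raise ValueError("duplicate state for one respondent")
    values = dict(zip(states, grid_index(group["ctto"].to_numpy())))
    offending = []
    for a, b in combinations(states, 2):
        for better, worse in ((a, b), (b, a)):
            if dominates(better, worse) and values[better] <= values[worse] - 10:
                offending.append((better, worse))
    return bool(offending), offending


def flag_worst_state(group: pd.DataFrame) -> bool | None:
    """True iff some state is valued strictly below 55555 (ties comply).

    Returns None (criterion skipped) when 55555 is absent.
    """
    values = dict(zip((str(s) for s in group["state"]), grid_index(group["ctto"])))
    if "55555" not in values:
        logger.warning("55555 absent for respondent; worst-state check skipped")
        return None
    worst = values["55555"]
    return any(v < worst for s, v in values.items() if s != "55555")


def interviewer_summary(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-interviewer response-distribution summary plus a pooled row."""
    deciles = [f"q{int(q * 100):02d}" for q in np.arange(0.1, 1.0, 0.1)]

    def _summarise(group: pd.DataFrame) -> pd.Series:
        idx = grid_index(group["ctto"].to_numpy())
        out = {
            "n_responses": len(group),
            "proportion_worse_than_dead": float(np.mean(idx < 0)),
            "proportion_at_minus1": float(np.mean(idx == -20)),
            "proportion_at_0": float(np.mean(idx == 0)),
            "proportion_at_1": float(np.mean(idx == 20)),
        }
        qs = np.quantile(group["ctto"].to_numpy(), np.arange(0.1, 1.0, 0.1))
        out.update(dict(zip(deciles, np.round(qs, 4))))
        return pd.Series(out)

    per = (
        responses.groupby("interviewer_id", sort=True)
        .apply(_summarise, include_groups=False)
        .reset_index()
    )
    pooled = _summarise(responses).to_frame().T
    pooled.insert(0, "interviewer_id", "pooled")
    summary = pd.concat([per, pooled], ignore_index=True)
    summary["n_responses"] = summary["n_responses"].astype(int)
    return summary


def run_qc(responses: pd.DataFrame) -> QCReport:
    """Apply all criteria and derive the analytic sample ids."""
    records = []
    for rid, group in responses.groupby("respondent_id", sort=True):
        rec: dict = {"respondent_id": rid}
        rec.update(flag_compliance(group))
        severe, pairs = flag_severe_inconsistency(group)
        rec["severe_inconsistency"] = severe
        rec["n_offending_pairs"] = len(pairs)
        worst = flag_worst_state(group)
        rec["worst_state_not_lowest"] = bool(worst) if worst is not None else False
        records.append(rec)
    flags = pd.DataFrame(records).set_index("respondent_id")
    analytic = tuple(flags.index[~flags["severe_inconsistency"]])
    if not analytic:
        logger.warning("all respondents flagged as severely inconsistent")
    return QCReport(
        respondent_flags=flags,
        interviewer_summary=interviewer_summary(responses),
        analytic_ids=analytic,
    )


def make_analytic_sample(
    responses: pd.DataFrame, report: QCReport
) -> pd.DataFrame:
    """Drop responses of severely inconsistent respondents (only that flag
    excludes); timing and worst-state violations are report-only."""
    keep = responses["respondent_id"].isin(report.analytic_ids)
    return responses[keep].reset_index(drop=True)
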