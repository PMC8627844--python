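"""Synthetic cTTO cohort generator.

Emulates the statistical structure of a 'lite'-protocol valuation study:
each respondent is assigned one block of 20 states and one interviewer, and
produces one composite time trade-off (cTTO) value per state. A latent value
is drawn from an additive ground truth (1 minus the state's dimension-level
decrements) plus a respondent-level random intercept and a severity-dependent
error, then censored at -1 (the lead-time TTO floor), clipped at 1 and
snapped to the instrument's 0.05 grid (41 admissible values). A configurable
fraction of respondents is made severely inconsistent — valuing a logically
better state at least 0.5 below a state it dominates — and task timings are
drawn so a configurable fraction breaches the protocol-compliance timers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .states import (
    DIMENSIONS,
    PARAM_NAMES,
    HealthState,
    as_state,
    dominates,
    misery_score,
)
from .design import ValuationDesign

GRID_STEP = 0.05
GRID_N = 41

RESPONSE_COLUMNS = [
    "respondent_id",
    "interviewer_id",
    "block_id",
    "state",
    "ctto",
    "wheelchair_seconds",
    "task_seconds",
    "flagged_inconsistent_truth",
]


@dataclass(frozen=True)
class CTTOResponse:
    """One elicited cTTO value for one respondent x state.

    ``flagged_inconsistent_truth`` is a simulation-only label marking
    respondents whose answers were perturbed into severe inconsistency.
    """

    respondent_id: int
    interviewer_id: int
    block_id: int
    state: HealthState
    ctto: float
    wheelchair_seconds: float
    task_seconds: float
    flagged_inconsistent_truth: bool = False

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.ctto <= 1.0 + 1e-9):
            raise ValueError(f"ctto {self.ctto} outside [-1, 1]")
        if abs(self.ctto / GRID_STEP - round(self.ctto / GRID_STEP)) > 1e-9:
            raise ValueError(f"ctto {self.ctto} is not on the 0.05 grid")

    @classmethod
    def from_row(cls, row) -> "CTTOResponse":
        return cls(
            respondent_id=int(row["respondent_id"]),
            interviewer_id=int(row["interviewer_id"]),
            block_id=int(row["block_id"]),
            state=as_state(str(row["state"])),
            ctto=float(row["ctto"]),
            wheelchair_seconds=float(row["wheelchair_seconds"]),
            task_seconds=float(row["task_seconds"]),
            flagged_inconsistent_truth=bool(
                row.get("flagged_inconsistent_truth", False)
            ),
        )


def elicitable_values() -> np.ndarray:
    """The 41 admissible cTTO values: -1.00, -0.95, ..., 0.95, 1.00."""
    return np.round(np.arange(-20, 21) * GRID_STEP, 2)


def snap_to_grid(value: float | np.ndarray) -> np.ndarray:
    """Nearest 0.05 multiple, ties rounded away from zero.

    A 1e-9 tolerance keeps binary-float representations of exact tie points
    (e.g. -0.925) on the away-from-zero side.
    """
    value = np.asarray(value, dtype=float)
    steps = np.copysign(np.floor(np.abs(value) / GRID_STEP + 0.5 + 1e-9), value)
    return steps * GRID_STEP


def observe(latent: float | np.ndarray) -> np.ndarray:
    """Observed cTTO from a latent value: censor at -1, clip at 1, snap to grid."""
    clipped = np.clip(np.asarray(latent, dtype=float), -1.0, 1.0)
    return snap_to_grid(clipped)


def grid_index(ctto: float | np.ndarray) -> np.ndarray:
    """Integer grid coordinate (ctto / 0.05, in -20..20); exact comparisons."""
    return np.rint(np.asarray(ctto, dtype=float) / GRID_STEP).astype(int)


@dataclass(frozen=True)
class GroundTruth:
    """The additive data-generating utility model.

    ``decrements`` maps each of the 20 (dimension, level>=2) cells to a
    non-negative value decrement; the value of a state is
    ``intercept - sum(decrements)``, so 11111 is worth ``intercept``.
    """

    decrements: Mapping[str, float]
    intercept: float = 1.0

    def __post_init__(self) -> None:
        missing = [p for p in PARAM_NAMES if p not in self.decrements]
        if missing:
            raise ValueError(f"missing decrement cells: {missing}")
        for dim in DIMENSIONS:
            vals = [self.decrements[f"{dim}{lev}"] for lev in range(2, 6)]
            if any(v < 0 for v in vals):
                raise ValueError(f"negative decrement in {dim}")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"decrements not level-monotone in {dim}")

    def value(self, state: HealthState | str) -> float:
        state = as_state(state)
        total = sum(
            self.decrements[f"{dim}{lev}"]
            for dim, lev in zip(DIMENSIONS, state.levels)
            if lev >= 2
        )
        return self.intercept - total

    def scaled(self, factor: float) -> "GroundTruth":
        """Same shape with all decrements scaled; used to modulate censoring."""
        return GroundTruth(
            decrements={k: v * factor for k, v in self.decrements.items()},
            intercept=self.intercept,
        )

    def as_vector(self) -> np.ndarray:
        return np.array([self.decrements[p] for p in PARAM_NAMES])


@dataclass(frozen=True)
class NoiseModel:
    """Severity-dependent response noise plus respondent heterogeneity.

    sigma(misery) = sigma_base * (1 + sigma_slope * (misery - 5)) in the
    default multiplicative mode, or sigma_base + sigma_slope * (misery - 5)
    in additive mode; ``tau`` is the SD of the respondent random intercept.
    """

    sigma_base: float = 0.15
    sigma_slope: float = 0.08
    mode: str = "multiplicative"
    tau: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        worst = self.sigma(25)
        if min(self.sigma(5), worst) <= 0:
            raise ValueError("sigma must stay positive over misery 5..25")

    def sigma(self, misery: int | np.ndarray) -> np.ndarray:
        misery = np.asarray(misery, dtype=float)
        if self.mode == "multiplicative":
            return self.sigma_base * (1.0 + self.sigma_slope * (misery - 5.0))
        return self.sigma_base + self.sigma_slope * (misery - 5.0)


def latent_value(
    state: HealthState | str,
    truth: GroundTruth,
    mu_i: float = 0.0,
    noise_draw: float = 0.0,
) -> float:
    """Latent (pre-censoring) cTTO value: truth value + random intercept + error."""
    return truth.value(state) + mu_i + noise_draw


def _inject_inconsistency(
    values: dict[HealthState, float], block: Sequence[HealthState], rng: np.random.Generator
) -> dict[HealthState, float]:
    """Force a severe inconsistency: pick a dominating pair (a better than b)
    with the best headroom and set ctto(a) <= ctto(b) - 0.5 - delta.

    The worse state's value is raised to at least 0.0 first so the injected
    better-state value stays above the -1 floor; all outputs stay on-grid.
    """
    pairs = [
        (a, b)
        for a in block
        for b in block
        if a != b and dominates(a, b)
    ]
    if not pairs:  # cannot occur for a valid lite block (mild dominates severe)
        raise RuntimeError("no dominating pair available for injection")
    a, b = max(pairs, key=lambda p: values[p[1]])
    new_b = max(values[b], 0.0)
    delta = GRID_STEP * rng.integers(1, 5)  # 0.05 .. 0.20
    values = dict(values)
    values[b] = float(snap_to_grid(new_b))
    values[a] = float(snap_to_grid(new_b - 0.5 - delta))
    return values


def simulate_cohort(
    design: ValuationDesign,
    n_respondents: int,
    truth: GroundTruth,
    noise: NoiseModel,
    inconsistency_rate: float = 0.0,
    n_interviewers: int = 6,
    seed: int = 0,
    compliance_violation_rate: float = 0.02,
    interviewer_shifts: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Simulate a full lite-protocol cohort; 20 responses per respondent.

    Returns a long-format frame with one row per (respondent, state); the
    ``flagged_inconsistent_truth`` column records the simulation-only label
    of respondents whose answers were perturbed into severe inconsistency.
    ``interviewer_shifts`` optionally adds a location shift to every latent
    value elicited by the given interviewer (1-based id), for exercising
    interviewer-effect diagnostics.
    """
    if n_respondents <= 0:
        raise ValueError("n_respondents must be positive")
    if not 0 <= inconsistency_rate < 1:
        raise ValueError("inconsistency_rate must be in [0, 1)")
    if design.kind != "lite":
        raise ValueError("simulate_cohort expects a lite design")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shifts = {int(k): float(v) for k, v in (interviewer_shifts or {}).items()}

    n_inconsistent = int(round(inconsistency_rate * n_respondents))
    inconsistent_ids = set(
        rng.choice(n_respondents, size=n_inconsistent, replace=False) + 1
    )

    rows: list[dict] = []
    for rid in range(1, n_respondents + 1):
        block_id = int(rng.integers(1, 11))
        interviewer_id = int(rng.integers(1, n_interviewers + 1))
        block = design.block(block_id)
        mu_i = rng.normal(0.0, noise.tau)
        shift = shifts.get(interviewer_id, 0.0)

        miseries = np.array([misery_score(s) for s in block])
        eps = rng.normal(0.0, noise.sigma(miseries))
        latents = np.array([truth.value(s) for s in block]) + mu_i + shift + eps
        observed = observe(latents)
        values = {s: float(v) for s, v in zip(block, observed)}

        flagged = rid in inconsistent_ids
        if flagged:
            values = _inject_inconsistency(values, block, rng)

        # timings: compliant by default; a configurable fraction breaches
        wheelchair = float(np.clip(rng.normal(320.0, 70.0), 190.0, None))
        task_secs = np.clip(rng.normal(90.0, 25.0, size=len(block)), 35.0, None)
        if rng.random() < compliance_violation_rate:
            if rng.random() < 0.5:
                wheelchair = float(rng.uniform(60.0, 175.0))
            else:
                task_secs = task_secs * (500.0 / task_secs.sum())

        order = rng.permutation(len(block))
        for pos in order:
            state = block[pos]
            rows.append(
                {
                    "respondent_id": rid,
                    "interviewer_id": interviewer_id,
                    "block_id": block_id,
                    "state": str(state),
                    "ctto": values[state],
                    "wheelchair_seconds": round(wheelchair, 1),
                    "task_seconds": round(float(task_secs[pos]), 1),
                    "flagged_inconsistent_truth": flagged,
                }
            )
    frame = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    frame["ctto"] = snap_to_grid(frame["ctto"].to_numpy())
    return frame


def write_responses(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    out["ctto"] = out["ctto"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)


def read_responses(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"state": str})
    frame["ctto"] = snap_to_grid(frame["ctto"].to_numpy())
    if "flagged_inconsistent_truth" in frame:
        frame["flagged_inconsistent_truth"] = frame[
            "flagged_inconsistent_truth"
        ].astype(bool)
    return frame
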