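"""Valuation designs: blocks of health states given to respondents.

The standard EQ-VT cTTO design is 10 blocks of 10 states (86 distinct):
every block holds the worst state 55555, one single-dimension mild state,
and eight block-unique states. The 'lite' design merges cyclically adjacent
block pairs (1&2, 2&3, ..., 10&1) into 10 blocks of 20 states and replaces
the duplicated 55555 in each merged block with one of the five severe states
45555, 54555, 55455, 55545, 55554 — giving 91 distinct states while each
respondent values 20 states instead of 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .states import (
    MILD_STATES,
    SEVERE_STATES,
    WORST_STATE,
    HealthState,
    as_state,
    misery_score,
)


class DesignError(ValueError):
    """Raised when a design violates its structural invariants."""


@dataclass(frozen=True)
class ValuationDesign:
    """An ordered list of blocks, each an ordered list of health states."""

    blocks: tuple[tuple[HealthState, ...], ...]
    kind: str  # "standard" | "lite"

    def __post_init__(self) -> None:
        if self.kind not in ("standard", "lite"):
            raise DesignError(f"unknown design kind {self.kind!r}")
        per_block = 10 if self.kind == "standard" else 20
        if len(self.blocks) != 10:
            raise DesignError(f"expected 10 blocks, got {len(self.blocks)}")
        for i, block in enumerate(self.blocks, start=1):
            if len(block) != per_block:
                raise DesignError(
                    f"block {i}: expected {per_block} states, got {len(block)}"
                )
            if block.count(WORST_STATE) != 1:
                raise DesignError(f"block {i}: 55555 must appear exactly once")

    @property
    def distinct_states(self) -> frozenset[HealthState]:
        return frozenset(s for block in self.blocks for s in block)

    def block(self, block_id: int) -> tuple[HealthState, ...]:
        """1-based block lookup."""
        return self.blocks[block_id - 1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"block_id": b + 1, "position": p + 1, "state": str(state)}
            for b, block in enumerate(self.blocks)
            for p, state in enumerate(block)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str) -> "ValuationDesign":
        frame = frame.sort_values(["block_id", "position"])
        blocks = tuple(
            tuple(HealthState.from_string(s) for s in grp["state"])
            for _, grp in frame.groupby("block_id", sort=True)
        )
        return cls(blocks=blocks, kind=kind)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str) -> "ValuationDesign":
        return cls.from_frame(pd.read_csv(path, dtype={"state": str}), kind)


def build_standard_design(
    unique_states: Sequence[HealthState | str],
    mild_states: Sequence[HealthState | str] = MILD_STATES,
    mild_assignment: Mapping[int, HealthState | str] | None = None,
) -> ValuationDesign:
    """Assemble the 10×10 standard design from its parts.

    ``unique_states``: 80 distinct states, 8 per block in listed order, none
    equal to 55555 or any mild state. ``mild_assignment`` maps 1-based block
    id to its mild state; each of the 5 mild states must cover exactly two
    blocks. Default assignment: mild state k to blocks k and k+5.
    """
    uniques = [as_state(s) for s in unique_states]
    milds = [as_state(s) for s in mild_states]
    if len(uniques) != 80 or len(set(uniques)) != 80:
        raise DesignError("need exactly 80 distinct block-unique states")
    for m in milds:
        if m not in MILD_STATES:
            raise DesignError(f"{m} is not a single-dimension mild state")
    forbidden = set(milds) | {WORST_STATE}
    if any(s in forbidden for s in uniques):
        raise DesignError("unique states must not include 55555 or a mild state")
    if mild_assignment is None:
        mild_assignment = {k: milds[(k - 1) % 5] for k in range(1, 11)}
    assignment = {int(b): as_state(s) for b, s in mild_assignment.items()}
    if sorted(assignment) != list(range(1, 11)):
        raise DesignError("mild assignment must cover blocks 1..10")
    counts = {m: list(assignment.values()).count(m) for m in milds}
    if any(c != 2 for c in counts.values()):
        raise DesignError(f"each mild state must serve exactly 2 blocks, got {counts}")

    blocks = []
    for b in range(1, 11):
        own = tuple(uniques[(b - 1) * 8 : b * 8])
        blocks.append((WORST_STATE, assignment[b]) + own)
    design = ValuationDesign(blocks=tuple(blocks), kind="standard")
    if len(design.distinct_states) != 86:
        raise DesignError(
            f"standard design must hold 86 distinct states, got "
            f"{len(design.distinct_states)}"
        )
    return design


DEFAULT_SEVERE_ASSIGNMENT: dict[int, HealthState] = {
    b: SEVERE_STATES[(b - 1) % 5] for b in range(1, 11)
}


def build_lite_design(
    standard: ValuationDesign,
    severe_assignment: Mapping[int, HealthState | str] | None = None,
) -> ValuationDesign:
    """Merge cyclically adjacent standard blocks into the 10×20 lite design.

    New block i is the union of standard blocks i and i+1 (block 11 wraps to
    1); the second source block's 55555 is replaced by the assigned severe
    state. Default assignment cycles the five severe states so each appears
    in exactly two lite blocks; all five must be used.
    """
    if standard.kind != "standard":
        raise DesignError("build_lite_design needs a standard design")
    if severe_assignment is None:
        severe_assignment = DEFAULT_SEVERE_ASSIGNMENT
    assignment = {int(b): as_state(s) for b, s in severe_assignment.items()}
    if sorted(assignment) != list(range(1, 11)):
        raise DesignError("severe assignment must cover blocks 1..10")
    for sev in assignment.values():
        if sev not in SEVERE_STATES:
            raise DesignError(f"{sev} is not one of the five severe states")
    if set(assignment.values()) != set(SEVERE_STATES):
        raise DesignError("all five severe states must be used")
    if standard.distinct_states & set(SEVERE_STATES):
        raise DesignError(
            "standard design already contains a severe substitution state"
        )

    blocks = []
    for b in range(1, 11):
        first = standard.block(b)
        second = list(standard.block(b % 10 + 1))
        second[second.index(WORST_STATE)] = assignment[b]
        blocks.append(first + tuple(second))
    lite = ValuationDesign(blocks=tuple(blocks), kind="lite")
    expected = len(standard.distinct_states) + 5
    if len(lite.distinct_states) != expected:
        raise DesignError(
            f"lite design should hold {expected} distinct states, got "
            f"{len(lite.distinct_states)}"
        )
    return lite


def generate_synthetic_standard_design(seed: int) -> ValuationDesign:
    """A structurally valid stand-in for the (unpublished) 86-state design.

    Draws 80 distinct states stratified by misery score so severities spread
    across the whole 6–24 range, then assembles them with the five canonical
    mild states and 55555. Deterministic for a given seed. Synthetic: the
    real EQ-VT state list is not reproduced.
    """
    rng = np.random.default_rng(seed)
    # severe substitution states stay out so the lite merge adds 5 new states
    forbidden = set(MILD_STATES) | set(SEVERE_STATES) | {WORST_STATE}
    # bucket all eligible states by misery score
    from .states import all_states

    buckets: dict[int, list[HealthState]] = {}
    for s in all_states():
        if s == HealthState((1, 1, 1, 1, 1)) or s in forbidden:
            continue
        buckets.setdefault(misery_score(s), []).append(s)
    chosen: list[HealthState] = []
    scores = sorted(buckets)
    # cycle severity strata so all are represented before any repeats
    idx = 0
    while len(chosen) < 80:
        score = scores[idx % len(scores)]
        pool = [s for s in buckets[score] if s not in chosen]
        if pool:
            chosen.append(pool[rng.integers(len(pool))])
        idx += 1
    order = rng.permutation(80)
    uniques = [chosen[i] for i in order]
    return build_standard_design(uniques)
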