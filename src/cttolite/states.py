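"""EQ-5D-5L health-state algebra.

An EQ-5D-5L health state is a profile over five dimensions — mobility (MO),
self-care (SC), usual activities (UA), pain/discomfort (PD) and
anxiety/depression (AD) — each scored on five levels, 1 (no problems) to 5
(unable/extreme problems). Profiles are written as 5-digit strings in the
instrument's canonical dimension order, e.g. ``"23514"``; there are
5**5 = 3125 of them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

DIMENSIONS: tuple[str, ...] = ("MO", "SC", "UA", "PD", "AD")
N_LEVELS = 5

#: Names of the 20 dimension-level decrement parameters, level 1 baseline.
PARAM_NAMES: tuple[str, ...] = tuple(
    f"{dim}{level}" for dim in DIMENSIONS for level in range(2, N_LEVELS + 1)
)


class InvalidStateError(ValueError):
    """Raised for malformed 5-digit profiles."""


@dataclass(frozen=True, order=True)
class HealthState:
    """One EQ-5D-5L profile: a 5-tuple of levels in canonical dimension order."""

    levels: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != len(DIMENSIONS):
            raise InvalidStateError(f"expected 5 levels, got {self.levels!r}")
        for lev in self.levels:
            if not (isinstance(lev, int) and 1 <= lev <= N_LEVELS):
                raise InvalidStateError(f"level {lev!r} outside 1..5 in {self.levels!r}")

    @classmethod
    def from_string(cls, code: str) -> "HealthState":
        code = str(code).strip()
        if len(code) != 5 or not code.isdigit():
            raise InvalidStateError(f"malformed state string {code!r}")
        return cls(tuple(int(c) for c in code))  # type: ignore[arg-type]

    def __str__(self) -> str:
        return "".join(str(lev) for lev in self.levels)

    def level(self, dimension: str) -> int:
        return self.levels[DIMENSIONS.index(dimension)]


FULL_HEALTH = HealthState((1, 1, 1, 1, 1))
WORST_STATE = HealthState((5, 5, 5, 5, 5))

#: The five "mild" states with slight problems in exactly one dimension.
MILD_STATES: tuple[HealthState, ...] = tuple(
    HealthState(tuple(2 if i == j else 1 for i in range(5)))  # type: ignore[arg-type]
    for j in range(5)
)

#: The five "severe" states with level 4 in exactly one dimension, 5 elsewhere.
SEVERE_STATES: tuple[HealthState, ...] = tuple(
    HealthState(tuple(4 if i == j else 5 for i in range(5)))  # type: ignore[arg-type]
    for j in range(5)
)


def as_state(state: "HealthState | str") -> HealthState:
    return state if isinstance(state, HealthState) else HealthState.from_string(state)


def misery_score(state: "HealthState | str") -> int:
    """Sum of the five severity levels (range 5–25), a crude severity index.

    E.g. state 23514 has misery score 2+3+5+1+4 = 15.
    """
    return sum(as_state(state).levels)


def dominates(a: "HealthState | str", b: "HealthState | str") -> bool:
    """True iff ``a`` is logically better than ``b``.

    ``a`` dominates ``b`` when every level of ``a`` is no worse (<=) than the
    corresponding level of ``b`` and the profiles differ. This is the strict
    partial order behind the severe-inconsistency QC rule.
    """
    sa, sb = as_state(a), as_state(b)
    return sa != sb and all(x <= y for x, y in zip(sa.levels, sb.levels))


def all_states() -> Iterator[HealthState]:
    """All 3125 profiles in lexicographic order (11111 first, 55555 last)."""
    for levels in itertools.product(range(1, N_LEVELS + 1), repeat=5):
        yield HealthState(levels)  # type: ignore[arg-type]


def is_mild_state(state: "HealthState | str", max_level2: int = 2) -> bool:
    """Mild-state predicate: all levels in {1, 2}, at most ``max_level2``
    dimensions at level 2, and not full health."""
    levels = as_state(state).levels
    n2 = sum(lev == 2 for lev in levels)
    return all(lev <= 2 for lev in levels) and 1 <= n2 <= max_level2
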