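"""Value sets: mapping all 3125 EQ-5D-5L profiles to anchored values.

A value set assigns each profile a societal value anchored at 1 (full
health, 11111) and 0 (dead): value(s) = 1 - sum of the profile's
dimension-level decrements, level 1 contributing nothing. The published
Ugandan coefficients (Tobit with constrained intercept, corrected for
heteroskedasticity; analytic N=492 and full N=545 samples) ship as a
packaged fixture. Coefficients are held as integer thousandths so sums of
3-decimal published values are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .states import (
    DIMENSIONS,
    PARAM_NAMES,
    HealthState,
    all_states,
    as_state,
)

_SCALE = 1000  # store decrements as integer thousandths


def _load_published() -> pd.DataFrame:
    with resources.files("cttolite.data").joinpath("uganda_decrements.csv").open() as fh:
        return pd.read_csv(fh)


def published_decrements(sample: str = "analytic") -> dict[str, float]:
    """The published Ugandan dimension-level decrements.

    ``sample`` is ``"analytic"`` (N=492, the primary value set) or ``"full"``
    (N=545 sensitivity re-fit).
    """
    table = _load_published()
    sub = table[table["sample"] == sample]
    if sub.empty:
        raise ValueError(f"unknown sample {sample!r}; use 'analytic' or 'full'")
    return {
        f"{row.dimension}{row.level}": float(row.decrement)
        for row in sub.itertuples()
    }


def published_standard_errors(sample: str = "analytic") -> dict[str, float]:
    table = _load_published()
    sub = table[table["sample"] == sample]
    return {f"{row.dimension}{row.level}": float(row.se) for row in sub.itertuples()}


@dataclass(frozen=True)
class ValueSet:
    """A full 3125-state value table derived from 20 decrements."""

    decrements_milli: tuple[int, ...]  # PARAM_NAMES order, integer thousandths
    provenance: str = "fitted"

    @classmethod
    def from_decrements(
        cls, decrements: Mapping[str, float], provenance: str = "fitted"
    ) -> "ValueSet":
        missing = [p for p in PARAM_NAMES if p not in decrements]
        if missing:
            raise ValueError(f"missing decrements: {missing}")
        milli = tuple(int(round(decrements[p] * _SCALE)) for p in PARAM_NAMES)
        if any(m < 0 for m in milli):
            warnings.warn("negative decrement: value set breaches face validity")
        return cls(decrements_milli=milli, provenance=provenance)

    @property
    def decrements(self) -> dict[str, float]:
        return {p: m / _SCALE for p, m in zip(PARAM_NAMES, self.decrements_milli)}

    def _state_milli(self, state: HealthState) -> int:
        total = 0
        for d, lev in enumerate(state.levels):
            if lev >= 2:
                total += self.decrements_milli[d * 4 + (lev - 2)]
        return _SCALE - total

    def value(self, state: HealthState | str) -> float:
        return self._state_milli(as_state(state)) / _SCALE

    def values(self) -> dict[str, float]:
        """All 3125 values, keyed by 5-digit state string."""
        return {str(s): self._state_milli(s) / _SCALE for s in all_states()}

    def summary(self) -> dict:
        vals = [(self._state_milli(s), str(s)) for s in all_states()]
        lo_val = min(v for v, _ in vals)
        lo = (lo_val, min(s for v, s in vals if v == lo_val))
        non_full = [t for t in vals if t[1] != "11111"]
        hi_val = max(v for v, _ in non_full)
        hi = (hi_val, min(s for v, s in non_full if v == hi_val))
        decs = self.decrements
        largest = max(PARAM_NAMES, key=lambda p: decs[p])
        smallest = min(PARAM_NAMES, key=lambda p: decs[p])
        return {
            "min_value": lo[0] / _SCALE,
            "min_state": lo[1],
            "max_value_non_full": hi[0] / _SCALE,
            "max_state_non_full": hi[1],
            "value_11111": self.value("11111"),
            "largest_decrement": (largest, decs[largest]),
            "smallest_decrement": (smallest, decs[smallest]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(str(s), self._state_milli(s) / _SCALE) for s in all_states()],
            columns=["state", "value"],
        )

    def to_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame["value"] = frame["value"].map(lambda v: f"{v:.5f}")
        frame.to_csv(path, index=False)


def score_state(state: HealthState | str, vs: ValueSet) -> float:
    """Value of one profile: 1 minus the sum of its dimension-level decrements.

    Under the published analytic-sample coefficients, state 23514 scores
    1 - (0.073 + 0.110 + 0.306 + 0 + 0.235) = 0.276.
    """
    return vs.value(state)


def build_value_set(
    decrements: Mapping[str, float], provenance: str = "fitted"
) -> ValueSet:
    return ValueSet.from_decrements(decrements, provenance=provenance)


def published_value_set(sample: str = "analytic") -> ValueSet:
    return ValueSet.from_decrements(
        published_decrements(sample), provenance=f"published-{sample}"
    )


def dimension_importance(vs: ValueSet) -> list[str]:
    """Dimensions ranked most-to-least important by their level-5 decrement.

    Ties break on the level-4 decrement, then canonical dimension order.
    """
    decs = vs.decrements
    order = sorted(
        range(5),
        key=lambda d: (-decs[f"{DIMENSIONS[d]}5"], -decs[f"{DIMENSIONS[d]}4"], d),
    )
    return [DIMENSIONS[d] for d in order]


def score_dataset(
    profiles: pd.DataFrame, vs: ValueSet, state_column: str | None = None
) -> tuple[pd.DataFrame, dict]:
    """Append a ``value`` column to a table of EQ-5D-5L profiles.

    The profile may be a 5-digit ``state`` column or five level columns named
    after the dimensions (MO, SC, UA, PD, AD). Invalid profiles get NaN and
    are counted in the summary.
    """
    frame = profiles.copy()
    if state_column is None:
        if "state" in frame.columns:
            state_column = "state"
        elif all(d in frame.columns for d in DIMENSIONS):
            frame["state"] = (
                frame[list(DIMENSIONS)].astype(int).astype(str).agg("".join, axis=1)
            )
            state_column = "state"
        else:
            raise ValueError("no 5-digit state column or five level columns found")

    def _score(code) -> float:
        try:
            return vs.value(as_state(str(code)))
        except Exception:
            return float("nan")

    frame["value"] = frame[state_column].map(_score)
    valid = frame["value"].dropna()
    summary = {
        "n": len(frame),
        "n_invalid": int(frame["value"].isna().sum()),
        "mean": float(valid.mean()) if len(valid) else float("nan"),
        "sd": float(valid.std(ddof=1)) if len(valid) > 1 else float("nan"),
        "histogram": np.histogram(valid, bins=np.arange(-1.2, 1.2001, 0.1))
        if len(valid)
        else None,
    }
    return frame, summary


def read_value_set(path: str | Path, provenance: str = "file") -> pd.DataFrame:
    return pd.read_csv(path, dtype={"state": str})
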