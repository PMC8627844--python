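"""Model evaluation: cross-validation, mild-state accuracy, selection.

Prediction errors are measured between model-predicted values and observed
per-state mean cTTO values, on the original cTTO scale. Two cross-validation
schemes mirror the study design: leave-out-by-state (each valued state
excluded in turn from estimation, then predicted) and leave-out-by-block
(all respondents of one block held out in turn). Mild-state accuracy
restricts full-data predictions to designed states with levels in {1, 2}
and at most two dimensions at level 2. Model selection gates on face
validity and ranks by mild-state MAE first — the criterion that separated
the candidates in practice — with state-CV and block-CV MAE and the RMSE
counterparts as tie-breakers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ValuationDesign
from .models import FittedModel, IdentifiabilityError, ModelSpec, check_face_validity, fit_model
from .states import is_mild_state

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionErrors:
    """MAE/RMSE over per-state prediction errors."""

    per_state: pd.DataFrame  # columns: state, observed, predicted, error
    n_failed_folds: int = 0

    def __post_init__(self) -> None:
        if self.rmse < self.mae - 1e-12:
            raise AssertionError("RMSE < MAE: inconsistent error aggregation")

    @property
    def errors(self) -> np.ndarray:
        return self.per_state["error"].to_numpy(dtype=float)

    @property
    def mae(self) -> float:
        if len(self.per_state) == 0:
            return float("nan")
        return float(np.mean(np.abs(self.errors)))

    @property
    def rmse(self) -> float:
        if len(self.per_state) == 0:
            return float("nan")
        return float(np.sqrt(np.mean(self.errors**2)))

    @property
    def n_states(self) -> int:
        return len(self.per_state)


def observed_state_means(responses: pd.DataFrame) -> pd.Series:
    """Arithmetic mean cTTO per state, on the original scale."""
    return responses.groupby(responses["state"].astype(str))["ctto"].mean()


def _errors_frame(
    states: Sequence[str], observed: Mapping[str, float], predicted: Mapping[str, float]
) -> pd.DataFrame:
    rows = [
        {
            "state": s,
            "observed": observed[s],
            "predicted": predicted[s],
            "error": predicted[s] - observed[s],
        }
        for s in states
    ]
    return pd.DataFrame(rows, columns=["state", "observed", "predicted", "error"])


def cv_leave_out_by_state(
    responses: pd.DataFrame, spec: ModelSpec, seed: int = 0
) -> PredictionErrors:
    """Exclude each valued state in turn, refit, predict the left-out state."""
    responses = responses.reset_index(drop=True)
    means = observed_state_means(responses)
    rows = []
    n_failed = 0
    for state in means.index:
        train = responses[responses["state"].astype(str) != state]
        try:
            fit = fit_model(train, spec, seed=seed)
        except IdentifiabilityError:
            logger.warning("state %s skipped: fold not identified", state)
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        pred = float(fit.predict_value([state])[0])
        rows.append({"state": state, "observed": means[state], "predicted": pred,
                     "error": pred - means[state]})
    return PredictionErrors(per_state=pd.DataFrame(rows), n_failed_folds=n_failed)


def cv_leave_out_by_block(
    responses: pd.DataFrame, spec: ModelSpec, seed: int = 0
) -> PredictionErrors:
    """Hold out all respondents of one block in turn.

    Left-out states are predicted from the remaining blocks and compared
    against observed means computed from the held-out responses only. States
    appearing in several blocks contribute once per fold (multiplicity
    pooling).
    """
    responses = responses.reset_index(drop=True)
    rows = []
    n_failed = 0
    for block_id in sorted(responses["block_id"].unique()):
        held = responses[responses["block_id"] == block_id]
        train = responses[responses["block_id"] != block_id]
        held_means = observed_state_means(held)
        try:
            fit = fit_model(train, spec, seed=seed)
        except IdentifiabilityError:
            logger.warning("block %s skipped: fold not identified", block_id)
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        preds = fit.predict_value(list(held_means.index))
        for state, pred in zip(held_means.index, preds):
            rows.append(
                {"state": state, "observed": held_means[state],
                 "predicted": float(pred), "error": float(pred) - held_means[state],
                 "block_id": block_id}
            )
    return PredictionErrors(per_state=pd.DataFrame(rows), n_failed_folds=n_failed)


def mild_state_errors(
    responses: pd.DataFrame,
    model: FittedModel,
    design: ValuationDesign | None = None,
) -> PredictionErrors:
    """Full-data prediction accuracy on the designed mild states.

    Mild states have every level in {1, 2} with at most two dimensions at
    level 2 (e.g. 11122 qualifies, 11123 and 21221 do not).
    """
    means = observed_state_means(responses)
    candidates = [s for s in means.index if is_mild_state(s)]
    if design is not None:
        designed = {str(s) for s in design.distinct_states}
        candidates = [s for s in candidates if s in designed]
    if not candidates:
        raise ValueError("no mild states present in the data")
    preds = dict(zip(candidates, map(float, model.predict_value(candidates))))
    return PredictionErrors(per_state=_errors_frame(candidates, means, preds))


@dataclass(frozen=True)
class ModelEvaluation:
    """One candidate's criteria: face validity and the error table rows."""

    name: str
    model: FittedModel
    mild: PredictionErrors | None = None
    by_state: PredictionErrors | None = None
    by_block: PredictionErrors | None = None

    @property
    def face_valid(self) -> bool:
        return check_face_validity(self.model)[0]

    def criteria(self) -> dict[str, float]:
        out: dict[str, float] = {"face_valid": float(self.face_valid)}
        for label, err in (("mild", self.mild), ("state_cv", self.by_state),
                           ("block_cv", self.by_block)):
            if err is not None:
                out[f"{label}_mae"] = err.mae
                out[f"{label}_rmse"] = err.rmse
        return out


def select_model(
    candidates: Sequence[ModelEvaluation],
    ranking: str = "mild_first",
) -> tuple[ModelEvaluation | None, pd.DataFrame]:
    """Gate on face validity, then rank by mild-state MAE with state-CV MAE,
    block-CV MAE and the RMSEs as successive tie-breakers.

    ``ranking="equal_weight"`` instead averages the available MAE criteria.
    Returns (winner, criterion table); winner is None when every candidate
    fails face validity. Deterministic in its inputs.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    if ranking not in ("mild_first", "equal_weight"):
        raise ValueError(f"unknown ranking {ranking!r}")
    rows = []
    for cand in candidates:
        row = {"model": cand.name}
        row.update(cand.criteria())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("model")

    valid = [c for c in candidates if c.face_valid]
    if not valid:
        logger.warning("no candidate passes face validity; no winner")
        return None, table

    def _key(c: ModelEvaluation):
        crit = c.criteria()
        if ranking == "equal_weight":
            maes = [v for k, v in crit.items() if k.endswith("_mae")]
            return (float(np.mean(maes)) if maes else np.inf, c.name)
        order = ["mild_mae", "state_cv_mae", "block_cv_mae",
                 "mild_rmse", "state_cv_rmse", "block_cv_rmse"]
        return tuple(crit.get(k, np.inf) for k in order) + (c.name,)

    ranked = sorted(valid, key=_key)
    table["rank"] = [
        next((i + 1 for i, c in enumerate(ranked) if c.name == name), np.nan)
        for name in table.index
    ]
    return ranked[0], table
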