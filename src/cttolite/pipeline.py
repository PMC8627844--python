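"""End-to-end pipeline: simulate -> qc -> fit -> evaluate -> select -> value set.

Also the sensitivity drivers: re-fit on the full (unfiltered) sample and
leave-one-interviewer-out re-estimation of the winning model.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, substream_seed
from .design import build_lite_design, generate_synthetic_standard_design
from .evaluation import (
    ModelEvaluation,
    cv_leave_out_by_block,
    cv_leave_out_by_state,
    mild_state_errors,
    select_model,
)
from .models import STUDY_MODELS, FittedModel, ModelSpec, fit_model
from .qc import make_analytic_sample, run_qc
from .simulate import GroundTruth, NoiseModel, simulate_cohort, write_responses
from .states import PARAM_NAMES
from .valueset import ValueSet, published_decrements

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def truth_from_config(config: PipelineConfig) -> GroundTruth:
    decs = published_decrements(config.truth_sample)
    return GroundTruth(decrements=decs).scaled(config.truth_scale)


def noise_from_config(config: PipelineConfig) -> NoiseModel:
    return NoiseModel(
        sigma_base=config.sigma_base,
        sigma_slope=config.sigma_slope,
        mode=config.noise_mode,
        tau=config.tau,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write artifacts under ``config.outdir`` and
    return the manifest. Re-running an identical config reproduces
    byte-identical artifacts (the manifest records no wall-clock times)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # partial artifacts stay on disk
            manifest["stages"][name] = "failed"
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True)
            )
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = "ok"
        logger.info("stage %-24s %8.3f s", name, time.perf_counter() - t0)
        return out

    def emit(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    def stage_simulate():
        standard = generate_synthetic_standard_design(
            substream_seed(config.seed, "design")
        )
        lite = build_lite_design(standard)
        lite.to_csv(outdir / "design_lite.csv")
        emit("design", outdir / "design_lite.csv")
        frame = simulate_cohort(
            lite,
            n_respondents=config.n_respondents,
            truth=truth_from_config(config),
            noise=noise_from_config(config),
            inconsistency_rate=config.inconsistency_rate,
            n_interviewers=config.n_interviewers,
            seed=substream_seed(config.seed, "cohort"),
            compliance_violation_rate=config.compliance_violation_rate,
        )
        write_responses(frame, outdir / "responses.csv")
        (outdir / "responses.meta.json").write_text(
            json.dumps(
                {"seed": config.seed, "n_respondents": config.n_respondents},
                sort_keys=True,
            )
        )
        emit("responses", outdir / "responses.csv")
        manifest["design"] = {"distinct_states": len(lite.distinct_states)}
        return frame, lite

    frame, lite = run_stage("simulate", stage_simulate)

    def stage_qc():
        report = run_qc(frame)
        report.write(outdir / "qc_respondents.csv", outdir / "qc_interviewers.csv")
        emit("qc_respondents", outdir / "qc_respondents.csv")
        emit("qc_interviewers", outdir / "qc_interviewers.csv")
        kept = frame if config.include_flagged else make_analytic_sample(frame, report)
        manifest["qc"] = {
            "n_respondents": int(frame["respondent_id"].nunique()),
            "n_flagged": report.n_flagged,
            "n_analytic": int(kept["respondent_id"].nunique()),
            "include_flagged": config.include_flagged,
        }
        return kept

    sample = run_stage("qc", stage_qc)

    def stage_fit():
        out: dict[str, FittedModel] = {}
        fit_seed = substream_seed(config.seed, "fitting")
        for name in config.models:
            spec = STUDY_MODELS[name] if name in STUDY_MODELS else ModelSpec(name)
            fitted = fit_model(sample, spec, seed=fit_seed)
            fitted.to_json(outdir / f"fit_{name}.json")
            emit(f"fit_{name}", outdir / f"fit_{name}.json")
            out[name] = fitted
        return out

    fits = run_stage("fit", stage_fit)

    def stage_evaluate():
        cands = []
        for name, fitted in fits.items():
            by_state = by_block = None
            if config.cross_validation in ("state", "both"):
                by_state = cv_leave_out_by_state(sample, fitted.spec)
            if config.cross_validation in ("block", "both"):
                by_block = cv_leave_out_by_block(sample, fitted.spec)
            cands.append(
                ModelEvaluation(
                    name=name,
                    model=fitted,
                    mild=mild_state_errors(sample, fitted, design=lite),
                    by_state=by_state,
                    by_block=by_block,
                )
            )
        winner, table = select_model(cands)
        table.to_csv(outdir / "evaluation.csv")
        emit("evaluation", outdir / "evaluation.csv")
        manifest["winner"] = winner.name if winner else None
        return winner

    winner = run_stage("evaluate", stage_evaluate)

    def stage_valueset():
        if winner is None:
            logger.warning("no winner; skipping value-set stage")
            return None
        value_set = ValueSet.from_decrements(
            winner.model.decrements20, provenance=f"fitted-{winner.name}"
        )
        value_set.to_csv(outdir / "valueset.csv")
        emit("valueset", outdir / "valueset.csv")
        summary = value_set.summary()
        manifest["valueset_summary"] = {
            k: v for k, v in summary.items() if not isinstance(v, tuple)
        }
        return value_set

    run_stage("valueset", stage_valueset)

    if config.leave_out_interviewers and winner is not None:
        def stage_sensitivity():
            table = sensitivity_interviewers(sample, winner.model)
            table.to_csv(outdir / "sensitivity_interviewers.csv", index=False)
            emit("sensitivity_interviewers", outdir / "sensitivity_interviewers.csv")
            return table

        run_stage("sensitivity_interviewers", stage_sensitivity)

    manifest["n_models_fitted"] = len(fits)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def sensitivity_interviewers(
    responses: pd.DataFrame, reference: FittedModel
) -> pd.DataFrame:
    """Re-fit the winning model excluding each interviewer in turn.

    Reports, per excluded interviewer, the maximum absolute coefficient
    deviation from the all-data fit (and its parameter).
    """
    interviewers = sorted(responses["interviewer_id"].unique())
    if len(interviewers) < 2:
        raise ValueError("need at least two interviewers")
    ref = np.array([reference.decrements20[p] for p in PARAM_NAMES])
    rows = []
    for iv in interviewers:
        sub = responses[responses["interviewer_id"] != iv]
        refit = fit_model(sub, reference.spec)
        dec = np.array([refit.decrements20[p] for p in PARAM_NAMES])
        dev = np.abs(dec - ref)
        worst = int(np.argmax(dev))
        row = {
            "excluded_interviewer": iv,
            "n_obs": refit.n_obs,
            "max_abs_deviation": float(dev[worst]),
            "max_deviation_param": PARAM_NAMES[worst],
            "converged": refit.converged,
        }
        row.update({p: float(d) for p, d in zip(PARAM_NAMES, dec)})
        rows.append(row)
    return pd.DataFrame(rows)
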