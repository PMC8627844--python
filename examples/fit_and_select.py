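"""Fit competing value-set models to a simulated cohort and pick a winner.

Fits the additive 20-parameter linear and Tobit models (the Tobit treats
values at the -1 floor as right-censored disutilities at 2) and the
heteroskedasticity-corrected constrained Tobit, then ranks face-valid
candidates by mild-state prediction accuracy. The winning model's
decrements define a value set over all 3125 profiles.
"""

from cttolite import (
    GroundTruth,
    ModelEvaluation,
    NoiseModel,
    STUDY_MODELS,
    ValueSet,
    build_lite_design,
    fit_model,
    generate_synthetic_standard_design,
    mild_state_errors,
    published_decrements,
    select_model,
    simulate_cohort,
)

lite = build_lite_design(generate_synthetic_standard_design(seed=0))
truth = GroundTruth(decrements=published_decrements("analytic"))
frame = simulate_cohort(lite, 400, truth, NoiseModel(), seed=7)

candidates = []
for name in ("model1", "model2", "model4_constrained"):
    fit = fit_model(frame, STUDY_MODELS[name])
    err = mild_state_errors(frame, fit, design=lite)
    candidates.append(ModelEvaluation(name=name, model=fit, mild=err))
    print(f"{name:18s} loglik={fit.loglik:9.1f} converged={fit.converged} "
          f"mild-state MAE={err.mae:.4f} PD5={fit.decrements20['PD5']:.3f}")

winner, table = select_model(candidates)
print(f"winner by mild-state accuracy: {winner.name}")
print("true PD5 decrement: 0.798 (the linear fits attenuate it under censoring)")

vs = ValueSet.from_decrements(winner.model.decrements20, provenance=winner.name)
s = vs.summary()
print(f"fitted value set: min {s['min_value']:.3f} at {s['min_state']}, "
      f"max ill-state value {s['max_value_non_full']:.3f} at {s['max_state_non_full']}")
# With censoring active (55555 latent mean -1.116) the Tobit-based models
# recover the severe decrements where the plain linear fit attenuates them.
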