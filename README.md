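# cttolite

A Python toolkit for the **'lite' EQ-5D-5L valuation protocol**: building
the lite composite time trade-off (cTTO) valuation design, simulating cTTO
cohorts with the statistical structure real valuation data exhibit, running
the standard quality-control criteria, estimating the six candidate
value-set regression models (including hand-written censored and
heteroskedastic likelihoods), selecting a model by cross-validation and
mild-state accuracy, and generating/scoring EQ-5D-5L value sets. The
published Ugandan value-set coefficients ship as a packaged fixture, so the
toolkit also works as a plain scoring engine.

It is written for health economists and biostatisticians who run or audit
EQ-5D-5L valuation studies, or who need Ugandan utility values for
QALY-based economic evaluation.

## Background

EQ-5D-5L describes health as a 5-digit profile over mobility (MO),
self-care (SC), usual activities (UA), pain/discomfort (PD) and
anxiety/depression (AD), each on levels 1–5 — 3 125 profiles in all. A
*value set* maps every profile `s` to a societal value anchored at 1 (full
health) and 0 (dead):

```
V(s) = 1 − Σ_d β_{d, level_d(s)}          (level 1 contributes 0)
```

The decrements β are estimated from cTTO interviews. Under the standard
protocol 1 000 respondents each value 10 states from a 10×10 design (86
distinct states). The **lite** protocol halves the sample: adjacent blocks
are merged into 10 blocks of 20 states, the duplicated worst state 55555 is
replaced by one of five severe states (45555 … 55554), giving 91 distinct
states, and 500 respondents × 20 tasks produce the same 10 000 responses.

cTTO values live on a 41-point grid from −1 to 1 in steps of 0.05 and are
left-censored at −1. Estimation is done on rescaled disutilities
`y = 1 − cTTO ∈ [0, 2]`, so censoring becomes right-censoring at 2 and
a constrained intercept (forcing `V(11111) = 1`) simply suppresses the
intercept to 0. Six candidate models are implemented:

| model | form |
|---|---|
| 1 | additive 20-parameter linear, respondent random intercept |
| 2 | additive 20-parameter Tobit (censored at −1) |
| 3 | linear, corrected for heteroskedasticity |
| 4 | Tobit, corrected for heteroskedasticity |
| 5 | multiplicative, 8 parameters (5 dimension weights × level multipliers L2–L4) |
| 6 | multiplicative, 9 parameters (adds L5 separating 'extreme' from 'unable' level-5 wording) |

Heteroskedasticity uses `log σ_j = γ0 + γ1 (misery_j − 5)`, where the
*misery score* is the sum of a state's five levels (5–25). Candidates must
be *face valid* (decrements non-decreasing in level within every dimension)
and are then ranked by mild-state prediction accuracy with leave-out-by-
state and leave-out-by-block cross-validation MAEs as tie-breakers.

## Worked example

```python
from cttolite import published_value_set, score_state, dimension_importance

vs = published_value_set("analytic")   # primary Ugandan value set (N = 492)
score_state("23514", vs)               # 0.276
score_state("55555", vs)               # -1.116  (the value-set floor)
score_state("11112", vs)               # 0.950   (best ill state)
dimension_importance(vs)               # ['PD', 'MO', 'SC', 'UA', 'AD']
```

The value 0.276 for state 23514 is `1 − (0.073 + 0.110 + 0.306 + 0 +
0.235)`: slight mobility problems, moderate self-care problems, unable to
do usual activities, no pain/discomfort, severe anxiety/depression.
Pain/discomfort carries the largest single decrement (PD5, 0.798) and
anxiety/depression level 2 the smallest (0.050).

A full simulation → QC → fit → select → value-set run:

```bash
cttolite run --seed 7 --out my_run      # or: python -m cttolite.cli ...
```

or from Python, see `examples/` — one short script per capability
(`score_profiles.py`, `build_lite_design.py`, `simulate_and_qc.py`,
`fit_and_select.py`). `examples/fit_and_select.py` prints, for a simulated
cohort of 400 respondents under the published decrements:

```
model1             loglik=    158.3 converged=True mild-state MAE=0.0119 PD5=0.770
model2             loglik=  -1150.3 converged=True mild-state MAE=0.0125 PD5=0.795
model4_constrained loglik=   -491.8 converged=True mild-state MAE=0.0192 PD5=0.809
winner by mild-state accuracy: model1
```

showing the censoring attenuation of the linear fit's severe decrements
(0.770 vs the true 0.798) and that the Tobit-based fits undo it.

## Layout

- `src/cttolite/states.py` — health-state algebra (misery score, dominance)
- `src/cttolite/design.py` — standard and lite valuation designs
- `src/cttolite/simulate.py` — synthetic cTTO cohort generator
- `src/cttolite/qc.py` — quality control and analytic-sample construction
- `src/cttolite/models.py` — the six regression models and likelihoods
- `src/cttolite/evaluation.py` — cross-validation, mild-state accuracy, selection
- `src/cttolite/valueset.py` — value-set generation, scoring, published fixture
- `src/cttolite/pipeline.py`, `config.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — the modelling assumptions and design choices
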