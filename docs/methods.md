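# Methods

## The estimation problem

A cTTO interview elicits, for each health state a respondent values, a
number on the grid −1.00, −0.95, …, 1.00 (41 values): positive values come
from conventional time trade-off, negative values from lead-time TTO for
worse-than-dead states, and the elicitation cannot go below −1. Values are
therefore *left-censored at −1*: a respondent who would trade even more
lead time is still recorded at −1. Dispersion also grows with severity —
mild states are valued in a narrow band near 1, severe states across most
of the scale — so residuals are heteroskedastic in severity.

All models are estimated on rescaled disutilities `y = 1 − cTTO ∈ [0, 2]`.
On this scale decrements are positive, censoring is right-censoring at 2,
and constraining the value of 11111 to 1 means suppressing the intercept
to 0. Predictions are mapped back to the value scale as `1 − ŷ`.

### Likelihoods

For the additive families the mean is `m_j = α + x_jᵀβ` with `x_j` the 20
dimension-level indicators (level 1 baseline). The hand-written censored
log-likelihood is

```
ℓ = Σ_{y_j < 2} log φ((y_j − m_j)/σ_j)/σ_j  +  Σ_{y_j = 2} log Φ((m_j − 2)/σ_j)
```

with `log Φ` evaluated via `scipy.special.log_ndtr` for tail stability.
The linear families use the same expression with the censoring set empty —
that is deliberate: ignoring the floor is what produces the attenuation the
Tobit corrects. Heteroskedastic variants set
`log σ_j = γ0 + γ1 (misery_j − 5)` with both γ estimated jointly by ML; the
homoskedastic variants estimate a single `log σ`. The multiplicative
families replace β by `β_dim × L_level` with the level-5 multiplier
normalised to 1 (the 9-parameter form estimates one extra L5 for PD/AD,
whose level-5 wording is 'extreme' rather than 'unable'); they are always
intercept-constrained, as a free intercept under the product structure has
no substantive interpretation here.

Optimisation is L-BFGS-B with analytic gradients for the additive families
and finite differences for the multiplicative ones (whose weights and
multipliers are bounded below at 0). Starting values come from the OLS fit;
if the first attempt does not converge, up to two restarts with 10 %
jittered starts keep the best optimum (convergence tolerances: `ftol`
1e−12, `gtol` 1e−8). Standard errors are inverse observed information
(numerical Hessian), with an optional respondent-clustered sandwich for the
additive families and a delta-method expansion to the 20 decrements for the
multiplicative ones. Observations at +1 (disutility 0) are treated as
uncensored: only the −1 floor is modelled. Model 1's respondent random
intercept is fitted by ML via `statsmodels.MixedLM`; the censored and
heteroskedastic fits are pooled with clustering available through the
sandwich option, mirroring how interval-regression routines are typically
used in valuation studies.

Degenerate inputs: a dimension-level cell never observed raises an
identifiability error naming the missing cells; invalid parameter points
(σ overflow, non-finite values) return −∞ to the optimizer rather than
raising; fits that still fail report `converged=False` and are dropped from
cross-validation aggregates with an explicit failed-fold count.

## The synthetic cohort generator

The generator stands in for raw valuation data, which valuation studies do
not deposit. It emulates:

* the lite design: 10 blocks × 20 states, 91 distinct, built by merging
  cyclically adjacent blocks of a synthetic 10×10 standard design (the real
  86-state list is proprietary to the protocol; the synthetic stand-in
  keeps its block structure and severity spread, stratified by misery
  score);
* one block and one interviewer per respondent, assigned uniformly;
* latent values `V(s) + μ_i + ε`, with respondent intercepts
  `μ_i ~ N(0, τ²)`, τ = 0.05 by default (mild clustering, chosen once as a
  realistic magnitude; valuation studies report modest within-respondent
  correlation), and `ε ~ N(0, σ(misery)²)` with
  `σ = 0.15 (1 + 0.08 (misery − 5))` by default, so mild-state dispersion
  (~0.16) is well below severe-state dispersion (~0.39);
* censoring at −1, clipping at 1, and snapping to the 0.05 grid with ties
  rounded away from zero (any deterministic tie rule works; this one is
  sign-symmetric; a 1e−9 tolerance keeps binary-float tie points on the
  away-from-zero side);
* severe-inconsistency injection: a configurable fraction of respondents
  has a dominating pair rewritten so the better state sits 0.55–0.70 below
  the worse one (the worse state is raised to ≥ 0 first so the injection
  never collides with the −1 floor — this guarantees detectability by
  construction);
* timings calibrated so a configurable fraction breaches the 3-minute
  wheelchair-example and 10-minute task compliance timers.

All randomness flows from one root seed through named substreams (design,
cohort, fitting), so stages are independently reproducible and identical
configurations produce byte-identical CSV artifacts.

### What the generator does *not* emulate

* **Internally coherent respondents.** Errors are independent across a
  respondent's tasks (apart from the shared intercept). Real respondents
  value states through a roughly monotone personal scale, so their errors
  are strongly positively correlated across tasks. Consequence: under the
  default noise the chance that some dominating pair among 20 tasks
  crosses the 0.5 rule by accident is high (~25 % of clean respondents),
  far above the ~10 % flagged in real fieldwork. The QC false-positive
  property (< 5 %) therefore holds — and is tested — at small noise;
  default-noise runs over-exclude, which the analytic-sample machinery
  handles but which should be kept in mind when reading simulated QC rates.
* **The ceiling at 1 in mild states.** With σ ≈ 0.16 at misery 6, a third
  of mild-state draws exceed 1 and are clipped, biasing simulated
  mild-state means downward by 0.02–0.04. Real mild-state responses
  cluster tightly just below 1 (observed means up to 0.96), with no such
  bias. Consequence: on simulated cohorts, free-intercept fits absorb the
  shift and beat constrained fits on mild-state MAE, while on real data the
  constrained heteroskedastic Tobit wins that criterion. Passing selection
  tests on simulated data therefore says the *procedure* (face-validity
  gate, mild-first ranking, deterministic tie-breaks) is correct, not that
  the same candidate must win as on real data.
* The iterative 0.5-year bisection routing of the elicitation (only its
  endpoint distribution is modelled), learning effects from the wheelchair
  example, EQ-VAS, demographics, and quota sampling.

## Evaluation and selection

Prediction errors compare model predictions with observed per-state mean
cTTO values on the original scale. Leave-out-by-state CV refits without
each valued state in turn (a fold whose removal breaks identifiability is
skipped with a warning); leave-out-by-block CV holds out all respondents of
one block and scores the held-out block's states against means computed
from the held-out responses only, pooling state errors across folds with
multiplicity (a state in several blocks contributes once per fold;
unique-state pooling is a one-line change on the per-state table). Mild
states are those with all levels in {1, 2} and at most two dimensions at
level 2 — 15 of the 3 125 profiles, of which a design contains however many
it contains (the synthetic standard design always carries the five
single-level-2 states). Selection gates on face validity (non-strict level
monotonicity of the 20 decrements), then ranks by mild-state MAE, breaking
ties by state-CV MAE, block-CV MAE, and the RMSE counterparts; mild
accuracy leads because it is the criterion that separates otherwise
near-identical candidates in this design, where 10 000 responses pin the
severe decrements tightly.

## Value sets and scoring

Published and fitted coefficient tables are held as integer thousandths, so
sums of 3-decimal coefficients are exact and the packaged Ugandan tables
reproduce bit-for-bit (the fixture is checksum-guarded). Both published
columns are included — the analytic sample (N = 492, the primary value
set, default) and the full sample (N = 545 sensitivity re-fit). Dimension
importance ranks by the level-5 decrement with level-4 and instrument-order
tie-breaks. Ties for extreme states resolve to the lexicographically
smallest state string; with the published coefficients all extremes are
unique (floor −1.116 at 55555, best ill state 0.950 at 11112).

## Problem sizes

Simulation experiments in the tests run at the protocol's native scale —
500 respondents × 20 tasks — with 10 seeds per model family for parameter
recovery and 5 replicates for the selection Monte Carlo; cross-validation
correctness is established on noise-free cohorts (2 respondents per block),
where every CV error is exactly zero, and behavioural CV checks use
moderate cohorts. These sizes were chosen so the full suite stays
desk-runnable while keeping Monte-Carlo error well inside the asserted
margins (at n = 10 000 the decrement standard errors are ≈ 0.01, against a
recovery tolerance of MAE < 0.02).

## Known limitations

* The heteroskedastic variance covariate (misery score) is one defensible
  choice; a per-indicator log-variance model is selectable by configuration
  but not the default.
* Pooled (rather than random-intercept) censored fits slightly understate
  uncertainty when τ > 0; respondent-clustered sandwich errors are the
  provided remedy.
* The generator's two realism gaps above mean simulated QC exclusion rates
  and simulated model-selection winners should not be read as predictions
  about real fieldwork.
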