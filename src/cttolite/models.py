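"""Regression models for cTTO value-set estimation.

All fitting happens on the rescaled disutility scale y = 1 - cTTO, which
lies in [0, 2]: full health maps to 0, the elicitation floor cTTO = -1 maps
to 2, so left-censoring of cTTO becomes right-censoring of y at 2, and
decrements come out positive. Six model families are supported:

* ``linear20`` — additive 20-parameter linear model (model 1 with a
  respondent-level Gaussian random intercept; pooled when
  ``random_intercept=False``), optionally corrected for heteroskedasticity
  (model 3);
* ``tobit20`` — additive 20-parameter Tobit with right-censoring at
  disutility 2 (model 2), optionally heteroskedastic (model 4);
* ``multiplicative8`` / ``multiplicative9`` — nonlinear models where the
  decrement for (dimension, level) is a dimension weight times a shared
  level multiplier, with the level-5 multiplier normalised to 1 (model 5);
  the 9-parameter form adds one L5 multiplier distinguishing the 'extreme'
  wording of level 5 in PD/AD from the 'unable' wording in MO/SC/UA
  (model 6). Both are intercept-constrained.

The heteroskedastic variance model is log sigma_j = gamma0 + gamma1 *
(misery_j - 5), two parameters estimated jointly by maximum likelihood.
Censored, heteroskedastic and multiplicative likelihoods are implemented
here directly; the random-intercept linear model is delegated to
statsmodels MixedLM (ML).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from .simulate import grid_index
from .states import DIMENSIONS, PARAM_NAMES, HealthState, as_state, misery_score

_LOG_2PI = np.log(2.0 * np.pi)
CENSOR_BOUND = 2.0  # disutility of cTTO = -1

FAMILIES = ("linear20", "tobit20", "multiplicative8", "multiplicative9")


class IdentifiabilityError(ValueError):
    """A dimension-level cell is never observed, or the design is singular."""


@dataclass(frozen=True)
class ModelSpec:
    """Which likelihood to maximise and under which constraints."""

    family: str
    heteroskedastic: bool = False
    intercept_mode: str = "constrained"
    random_intercept: bool = False
    variance_covariate: str = "misery"  # "misery" | "indicators"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.variance_covariate not in ("misery", "indicators"):
            raise ValueError(f"unknown variance covariate {self.variance_covariate!r}")
        if self.intercept_mode not in ("free", "constrained"):
            raise ValueError(f"unknown intercept mode {self.intercept_mode!r}")
        if self.family.startswith("multiplicative") and self.intercept_mode != "constrained":
            raise ValueError("multiplicative models are always intercept-constrained")
        if self.random_intercept and self.family != "linear20":
            raise ValueError("random intercept is only supported for linear20")
        if self.random_intercept and self.heteroskedastic:
            raise ValueError(
                "random intercept and heteroskedastic variance cannot be combined"
            )

    @property
    def is_multiplicative(self) -> bool:
        return self.family.startswith("multiplicative")

    @property
    def censored(self) -> bool:
        return self.family == "tobit20"

    def label(self) -> str:
        bits = [self.family]
        if self.heteroskedastic:
            bits.append("het")
        bits.append(self.intercept_mode)
        if self.random_intercept:
            bits.append("ri")
        return "/".join(bits)


#: The study's candidate models 1-6 (constrained/unconstrained variants
#: where both were reported).
STUDY_MODELS: dict[str, ModelSpec] = {
    "model1": ModelSpec("linear20", intercept_mode="free", random_intercept=True),
    "model2": ModelSpec("tobit20", intercept_mode="free"),
    "model3_free": ModelSpec("linear20", heteroskedastic=True, intercept_mode="free"),
    "model3_constrained": ModelSpec("linear20", heteroskedastic=True),
    "model4_free": ModelSpec("tobit20", heteroskedastic=True, intercept_mode="free"),
    "model4_constrained": ModelSpec("tobit20", heteroskedastic=True),
    "model5": ModelSpec("multiplicative8"),
    "model6": ModelSpec("multiplicative9"),
}


def rescale(ctto: float | np.ndarray) -> np.ndarray:
    """Map cTTO values in [-1, 1] to disutilities 1 - cTTO in [0, 2]."""
    arr = np.asarray(ctto, dtype=float)
    if np.any(arr < -1 - 1e-9) or np.any(arr > 1 + 1e-9):
        raise ValueError("cTTO values must lie in [-1, 1]")
    return 1.0 - arr


def design_row(state: HealthState | str) -> np.ndarray:
    """The 20 dimension-level indicators of a state, level 1 baseline."""
    state = as_state(state)
    row = np.zeros(20)
    for d, lev in enumerate(state.levels):
        if lev >= 2:
            row[d * 4 + (lev - 2)] = 1.0
    return row


def design_matrix(states: Sequence[HealthState | str]) -> np.ndarray:
    return np.vstack([design_row(s) for s in states])


@dataclass
class ModelData:
    """Pre-assembled arrays for one estimation problem."""

    X: np.ndarray  # (n, 20) indicators
    y: np.ndarray  # rescaled disutilities in [0, 2]
    censored: np.ndarray  # bool, observation at the bound (cTTO == -1)
    misery: np.ndarray  # per-observation misery score
    groups: np.ndarray  # respondent ids
    states: np.ndarray  # 5-digit strings


def prepare_data(responses: pd.DataFrame) -> ModelData:
    states = responses["state"].astype(str).to_numpy()
    X = design_matrix(states)
    ctto = responses["ctto"].to_numpy(dtype=float)
    y = rescale(ctto)
    censored = grid_index(ctto) == -20
    misery = np.array([misery_score(s) for s in states], dtype=float)
    groups = (
        responses["respondent_id"].to_numpy()
        if "respondent_id" in responses
        else np.arange(len(responses))
    )
    return ModelData(X=X, y=y, censored=censored, misery=misery, groups=groups,
                     states=states)


def check_identified(data: ModelData, after_removal_of: str | None = None) -> None:
    counts = data.X.sum(axis=0)
    missing = [PARAM_NAMES[i] for i in range(20) if counts[i] == 0]
    if missing:
        raise IdentifiabilityError(
            f"dimension-level cells never observed: {', '.join(missing)}"
        )
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(data.y)), data.X]))
    if rank < 21:
        raise IdentifiabilityError("design matrix is rank-deficient")


# ---------------------------------------------------------------------------
# parameter packing


def _n_mean_params(spec: ModelSpec) -> int:
    free = spec.intercept_mode == "free"
    if spec.is_multiplicative:
        return 5 + 3 + (1 if spec.family == "multiplicative9" else 0)
    return 20 + (1 if free else 0)


def _n_var_params(spec: ModelSpec) -> int:
    if not spec.heteroskedastic:
        return 1
    return 21 if spec.variance_covariate == "indicators" else 2


def param_names(spec: ModelSpec) -> list[str]:
    names: list[str] = []
    if spec.intercept_mode == "free" and not spec.is_multiplicative:
        names.append("alpha")
    if spec.is_multiplicative:
        names += [f"beta_{d}" for d in DIMENSIONS] + ["L2", "L3", "L4"]
        if spec.family == "multiplicative9":
            names.append("L5")
    else:
        names += list(PARAM_NAMES)
    if not spec.heteroskedastic:
        names.append("log_sigma")
    elif spec.variance_covariate == "indicators":
        names += ["gamma0"] + [f"gamma_{p}" for p in PARAM_NAMES]
    else:
        names += ["gamma0", "gamma1"]
    return names


def expand_multiplicative(theta: np.ndarray, family: str) -> np.ndarray:
    """Expand (beta5, L2..L4[, L5]) into the 20 dimension-level decrements."""
    beta = np.asarray(theta[:5], dtype=float)
    L = {2: theta[5], 3: theta[6], 4: theta[7]}
    if family == "multiplicative9":
        L5 = theta[8]
        lvl5 = np.array([1.0, 1.0, 1.0, L5, L5])  # MO, SC, UA unable; PD, AD extreme
    elif family == "multiplicative8":
        lvl5 = np.ones(5)
    else:
        raise ValueError(family)
    d20 = np.empty(20)
    for d in range(5):
        for lev in range(2, 5):
            d20[d * 4 + (lev - 2)] = beta[d] * L[lev]
        d20[d * 4 + 3] = beta[d] * lvl5[d]
    return d20


def multiplicative_ground_truth(
    beta: Sequence[float], L: Sequence[float], L5: float | None = None
):
    """A GroundTruth whose decrements follow the multiplicative structure
    (dimension weights x level multipliers); for recovery experiments."""
    from .simulate import GroundTruth

    family = "multiplicative9" if L5 is not None else "multiplicative8"
    theta = np.array(list(beta) + list(L) + ([L5] if L5 is not None else []))
    d20 = expand_multiplicative(theta, family)
    return GroundTruth(decrements=dict(zip(PARAM_NAMES, d20)))


def _mean_and_sigma(
    params: np.ndarray, data: ModelData, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear predictor m_j, sigma_j and the expanded decrements."""
    params = np.asarray(params, dtype=float)
    k = _n_mean_params(spec)
    mean_p, var_p = params[:k], params[k:]
    alpha = 0.0
    if spec.is_multiplicative:
        d20 = expand_multiplicative(mean_p, spec.family)
    elif spec.intercept_mode == "free":
        alpha, d20 = mean_p[0], mean_p[1:]
    else:
        d20 = mean_p
    m = alpha + data.X @ d20
    with np.errstate(over="ignore"):
        if not spec.heteroskedastic:
            sigma = np.full(len(data.y), np.exp(var_p[0]))
        elif spec.variance_covariate == "indicators":
            sigma = np.exp(var_p[0] + data.X @ var_p[1:])
        else:
            sigma = np.exp(var_p[0] + var_p[1] * (data.misery - 5.0))
    return m, sigma, d20


def censored_loglik(
    params: np.ndarray, data: ModelData, spec: ModelSpec
) -> float:
    """Log-likelihood on the disutility scale with right-censoring at 2.

    Uncensored observations contribute a Gaussian log density; observations
    at the bound contribute log P(latent >= 2) = log Phi((m - 2) / sigma).
    Families that ignore censoring (linear20) treat every observation as
    uncensored. Invalid parameters (non-finite, sigma overflow) yield -inf
    so optimizers reject them rather than crash.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        return -np.inf
    m, sigma, _ = _mean_and_sigma(params, data, spec)
    if not (np.all(np.isfinite(sigma)) and np.all(sigma > 0)):
        return -np.inf
    cens = data.censored if spec.censored else np.zeros(len(data.y), dtype=bool)
    z = (data.y - m) / sigma
    ll_unc = -np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * z * z
    total = float(ll_unc[~cens].sum())
    if cens.any():
        u = (m[cens] - CENSOR_BOUND) / sigma[cens]
        total += float(special.log_ndtr(u).sum())
    if not np.isfinite(total):
        return -np.inf
    return total


def _loglik_and_grad(
    params: np.ndarray, data: ModelData, spec: ModelSpec
) -> tuple[float, np.ndarray]:
    """Analytic score for the linear-predictor families (additive models)."""
    m, sigma, _ = _mean_and_sigma(params, data, spec)
    if not (np.all(np.isfinite(sigma)) and np.all(sigma > 0) and np.all(np.isfinite(m))):
        return -np.inf, np.zeros(len(params))
    cens = data.censored if spec.censored else np.zeros(len(data.y), dtype=bool)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        z = (data.y - m) / sigma

        dll_dm = np.empty(len(data.y))
        dll_dlogs = np.empty(len(data.y))
        ll = np.empty(len(data.y))

        unc = ~cens
        ll[unc] = -np.log(sigma[unc]) - 0.5 * _LOG_2PI - 0.5 * z[unc] ** 2
        dll_dm[unc] = z[unc] / sigma[unc]
        dll_dlogs[unc] = z[unc] ** 2 - 1.0
        if cens.any():
            u = (m[cens] - CENSOR_BOUND) / sigma[cens]
            log_phi = -0.5 * _LOG_2PI - 0.5 * u * u
            log_Phi = special.log_ndtr(u)
            ratio = np.exp(log_phi - log_Phi)  # phi(u)/Phi(u), stable
            ll[cens] = log_Phi
            dll_dm[cens] = ratio / sigma[cens]
            dll_dlogs[cens] = -ratio * u

        free = spec.intercept_mode == "free"
        pieces = []
        if free:
            pieces.append(dll_dm.sum())
        pieces.extend(data.X.T @ dll_dm)
        pieces.append(dll_dlogs.sum())
        if spec.heteroskedastic:
            if spec.variance_covariate == "indicators":
                pieces.extend(data.X.T @ dll_dlogs)
            else:
                pieces.append(dll_dlogs @ (data.misery - 5.0))
        total = float(ll.sum())
        grad = np.array(pieces)
    if not np.isfinite(total) or not np.all(np.isfinite(grad)):
        return -np.inf, np.zeros(len(params))
    return total, grad


def _score_matrix(
    params: np.ndarray, data: ModelData, spec: ModelSpec
) -> np.ndarray:
    """Per-observation scores (for cluster-robust covariance); additive only."""
    m, sigma, _ = _mean_and_sigma(params, data, spec)
    cens = data.censored if spec.censored else np.zeros(len(data.y), dtype=bool)
    z = (data.y - m) / sigma
    dll_dm = np.where(cens, 0.0, z / sigma)
    dll_dlogs = np.where(cens, 0.0, z * z - 1.0)
    if cens.any():
        u = (m[cens] - CENSOR_BOUND) / sigma[cens]
        ratio = np.exp(-0.5 * _LOG_2PI - 0.5 * u * u - special.log_ndtr(u))
        dll_dm[cens] = ratio / sigma[cens]
        dll_dlogs[cens] = -ratio * u
    cols = []
    if spec.intercept_mode == "free":
        cols.append(dll_dm)
    cols.extend((data.X * dll_dm[:, None]).T)
    cols.append(dll_dlogs)
    if spec.heteroskedastic:
        if spec.variance_covariate == "indicators":
            cols.extend((data.X * dll_dlogs[:, None]).T)
        else:
            cols.append(dll_dlogs * (data.misery - 5.0))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# fitted-model container


@dataclass
class FittedModel:
    """Estimates of one model, with the 20 decrements always materialised."""

    spec: ModelSpec
    decrements20: dict[str, float]
    raw_params: dict[str, float]
    loglik: float
    se: dict[str, float]
    se_decrements20: dict[str, float]
    n_obs: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def alpha(self) -> float:
        """Rescaled-scale intercept (0 for constrained fits)."""
        return self.raw_params.get("alpha", 0.0)

    def predict_disutility(self, states: Sequence[HealthState | str]) -> np.ndarray:
        d20 = np.array([self.decrements20[p] for p in PARAM_NAMES])
        return self.alpha + design_matrix(states) @ d20

    def predict_value(self, states: Sequence[HealthState | str]) -> np.ndarray:
        """Predicted cTTO-scale values (1 - predicted disutility)."""
        return 1.0 - self.predict_disutility(states)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": asdict(self.spec),
            "decrements20": self.decrements20,
            "raw_params": self.raw_params,
            "loglik": self.loglik,
            "se": self.se,
            "se_decrements20": self.se_decrements20,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedModel":
        payload = json.loads(Path(path).read_text())
        payload["spec"] = ModelSpec(**payload["spec"])
        return cls(**payload)


def check_face_validity(model: FittedModel) -> tuple[bool, list[tuple[str, int]]]:
    """Face validity: decrements non-decreasing in level within each dimension
    (non-strict) and non-negative; returns violating (dimension, level) pairs."""
    violations: list[tuple[str, int]] = []
    for dim in DIMENSIONS:
        prev = 0.0
        for lev in range(2, 6):
            cur = model.decrements20[f"{dim}{lev}"]
            if cur < prev - 1e-12:
                violations.append((dim, lev))
            prev = cur
    return not violations, violations


# ---------------------------------------------------------------------------
# fitting


def _ols_start(data: ModelData, spec: ModelSpec) -> np.ndarray:
    free = spec.intercept_mode == "free" and not spec.is_multiplicative
    X = np.column_stack([np.ones(len(data.y)), data.X]) if free else data.X
    beta, *_ = np.linalg.lstsq(X, data.y, rcond=None)
    resid = data.y - X @ beta
    sigma = max(float(resid.std()), 1e-3)
    if spec.is_multiplicative:
        d20 = beta.reshape(5, 4)
        b5 = np.clip(d20[:, 3], 0.05, None)
        theta = list(b5)
        for lev in (2, 3, 4):
            theta.append(float(np.clip(np.mean(d20[:, lev - 2] / b5), 0.02, 2.0)))
        if spec.family == "multiplicative9":
            theta.append(1.0)
        start = np.array(theta)
    else:
        start = beta
    var = [np.log(sigma)] + [0.0] * (_n_var_params(spec) - 1)
    return np.concatenate([start, var])


def _fit_ml(
    data: ModelData,
    spec: ModelSpec,
    start: np.ndarray | None = None,
    n_restarts: int = 2,
    cluster_se: bool = False,
    seed: int = 0,
) -> FittedModel:
    """Maximum likelihood for all pooled families via L-BFGS-B.

    Additive families use the analytic score; multiplicative families use
    finite-difference gradients with non-negativity bounds on the weights
    and level multipliers. Multi-start: jittered restarts keep the best
    optimum found.
    """
    if start is None:
        start = _ols_start(data, spec)
    names = param_names(spec)
    analytic = not spec.is_multiplicative

    if analytic:
        def objective(p):
            ll, g = _loglik_and_grad(p, data, spec)
            return -ll, -g
    else:
        def objective(p):
            return -censored_loglik(p, data, spec)

    bounds = None
    if spec.is_multiplicative:
        k = _n_mean_params(spec)
        bounds = [(1e-6, None)] * k + [(None, None)] * _n_var_params(spec)

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(1 + n_restarts):
        x0 = start if attempt == 0 else start * (1 + 0.1 * rng.standard_normal(len(start)))
        res = optimize.minimize(
            objective,
            x0,
            jac=analytic or None,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if attempt == 0 and res.success:
            break
    assert best is not None
    theta = best.x
    ll = -float(best.fun)

    k = _n_mean_params(spec)
    if spec.is_multiplicative:
        d20 = expand_multiplicative(theta[:k], spec.family)
    elif spec.intercept_mode == "free":
        d20 = theta[1:k]
    else:
        d20 = theta[:k]

    # observed-information covariance; cluster sandwich optionally
    se = np.full(len(theta), np.nan)
    se_d20 = np.full(20, np.nan)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = numdiff.approx_hess1(theta, lambda p: -censored_loglik(p, data, spec))
            cov = np.linalg.inv(hess)
        if cluster_se and not spec.is_multiplicative:
            S = _score_matrix(theta, data, spec)
            frame = pd.DataFrame(S)
            frame["g"] = data.groups
            G = frame.groupby("g").sum().to_numpy()
            cov = cov @ (G.T @ G) @ cov
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        if spec.is_multiplicative:
            J = numdiff.approx_fprime(
                theta[:k], lambda t: expand_multiplicative(t, spec.family)
            )
            cov_d20 = J @ cov[:k, :k] @ J.T
            se_d20 = np.sqrt(np.clip(np.diag(cov_d20), 0, None))
        else:
            off = 1 if spec.intercept_mode == "free" else 0
            se_d20 = se[off : off + 20]
    except np.linalg.LinAlgError:
        pass

    raw = dict(zip(names, map(float, theta)))
    diagnostics = {
        "optimizer_message": str(best.message),
        "n_censored": int(data.censored.sum()) if spec.censored else 0,
        "n_iter": int(best.nit),
        "seed": int(seed),
    }
    return FittedModel(
        spec=spec,
        decrements20=dict(zip(PARAM_NAMES, map(float, d20))),
        raw_params=raw,
        loglik=ll,
        se=dict(zip(names, map(float, se))),
        se_decrements20=dict(zip(PARAM_NAMES, map(float, se_d20))),
        n_obs=len(data.y),
        converged=bool(best.success),
        diagnostics=diagnostics,
    )


def _fit_mixed(data: ModelData, spec: ModelSpec) -> FittedModel:
    """Random-intercept linear model via statsmodels MixedLM (ML)."""
    import statsmodels.api as sm

    free = spec.intercept_mode == "free"
    X = np.column_stack([np.ones(len(data.y)), data.X]) if free else data.X
    names = (["alpha"] if free else []) + list(PARAM_NAMES)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(data.y, X, groups=data.groups)
        # lbfgs occasionally lands on a singular profiled Hessian; fall back
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                result = model.fit(reml=False, method=method)
                break
            except np.linalg.LinAlgError:
                continue
    if result is None:
        raise RuntimeError("random-intercept fit failed under all optimizers")
    fe = np.asarray(result.fe_params)
    fe_se = np.asarray(result.bse_fe)
    d20 = fe[1:] if free else fe
    se_d20 = fe_se[1:] if free else fe_se
    tau = float(np.sqrt(max(float(np.asarray(result.cov_re).ravel()[0]), 0.0)))
    sigma = float(np.sqrt(result.scale))
    raw = dict(zip(names, map(float, fe)))
    raw.update({"tau": tau, "log_sigma": float(np.log(sigma))})
    se = dict(zip(names, map(float, fe_se)))
    return FittedModel(
        spec=spec,
        decrements20=dict(zip(PARAM_NAMES, map(float, d20))),
        raw_params=raw,
        loglik=float(result.llf),
        se=se,
        se_decrements20=dict(zip(PARAM_NAMES, map(float, se_d20))),
        n_obs=len(data.y),
        converged=bool(result.converged),
        diagnostics={"sigma": sigma, "tau": tau},
    )


def fit_model(
    responses: pd.DataFrame,
    spec: ModelSpec,
    start: np.ndarray | None = None,
    cluster_se: bool = False,
    seed: int = 0,
) -> FittedModel:
    """Fit one model family to a response table (columns state, ctto,
    respondent_id)."""
    data = prepare_data(responses)
    check_identified(data)
    if spec.random_intercept:
        return _fit_mixed(data, spec)
    return _fit_ml(data, spec, start=start, cluster_se=cluster_se, seed=seed)


def fit_linear20(
    responses: pd.DataFrame, spec: ModelSpec | None = None, **kw
) -> FittedModel:
    spec = spec or ModelSpec("linear20", intercept_mode="free", random_intercept=True)
    if spec.family != "linear20":
        raise ValueError("fit_linear20 requires a linear20 spec")
    return fit_model(responses, spec, **kw)


def fit_tobit20(
    responses: pd.DataFrame, spec: ModelSpec | None = None, **kw
) -> FittedModel:
    spec = spec or ModelSpec("tobit20", intercept_mode="free")
    if spec.family != "tobit20":
        raise ValueError("fit_tobit20 requires a tobit20 spec")
    return fit_model(responses, spec, **kw)


def fit_multiplicative(
    responses: pd.DataFrame, spec: ModelSpec | None = None, **kw
) -> FittedModel:
    spec = spec or ModelSpec("multiplicative8")
    if not spec.is_multiplicative:
        raise ValueError("fit_multiplicative requires a multiplicative spec")
    return fit_model(responses, spec, **kw)
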