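import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import cttolite as ct
from cttolite.models import (
    CENSOR_BOUND,
    FittedModel,
    IdentifiabilityError,
    ModelData,
    ModelSpec,
    censored_loglik,
    check_face_validity,
    design_row,
    expand_multiplicative,
    fit_model,
    multiplicative_ground_truth,
    param_names,
    prepare_data,
    rescale,
)
from cttolite.states import PARAM_NAMES

from conftest import exact_responses


def _toy_data(rng, n=20, censor_fraction=0.3):
    states = rng.choice(["11112", "23514", "55555", "21345", "11122"], size=n)
    X = np.vstack([design_row(s) for s in states])
    y = rng.uniform(0.0, 2.0, size=n)
    censored = np.zeros(n, dtype=bool)
    k = int(censor_fraction * n)
    censored[:k] = True
    y[censored] = CENSOR_BOUND
    misery = np.array([ct.misery_score(s) for s in states], dtype=float)
    return ModelData(X=X, y=y, censored=censored, misery=misery,
                     groups=np.arange(n), states=states)


class TestRescale:
    @pytest.mark.parametrize("ctto,dis", [(1.0, 0.0), (-1.0, 2.0), (0.276, 0.724)])
    def test_examples(self, ctto, dis):
        assert rescale(ctto) == pytest.approx(dis)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rescale(1.2)


class TestDesignRow:
    def test_full_health_is_baseline(self):
        assert not design_row("11111").any()

    def test_worked_profile(self):
        row = design_row("23514")
        on = {PARAM_NAMES[i] for i in np.flatnonzero(row)}
        assert on == {"MO2", "SC3", "UA5", "AD4"}  # PD at level 1 contributes 0

    def test_worst_state_hits_all_level5_cells(self):
        row = design_row("55555")
        assert row.sum() == 5
        on = {PARAM_NAMES[i] for i in np.flatnonzero(row)}
        assert on == {"MO5", "SC5", "UA5", "PD5", "AD5"}


class TestCensoredLoglik:
    def test_equals_gaussian_when_uncensored(self):
        rng = np.random.default_rng(0)
        data = _toy_data(rng, censor_fraction=0.0)
        spec = ModelSpec("tobit20", intercept_mode="free")
        params = np.concatenate([[0.1], rng.uniform(0, 0.2, 20), [np.log(0.3)]])
        m = 0.1 + data.X @ params[1:21]
        expected = stats.norm.logpdf(data.y, loc=m, scale=0.3).sum()
        assert censored_loglik(params, data, spec) == pytest.approx(expected, abs=1e-10)

    def test_bound_observation_with_mean_at_bound(self):
        data = ModelData(
            X=design_row("55555")[None, :],
            y=np.array([2.0]),
            censored=np.array([True]),
            misery=np.array([25.0]),
            groups=np.array([1]),
            states=np.array(["55555"]),
        )
        spec = ModelSpec("tobit20")
        d20 = np.zeros(20)
        d20[[3, 7, 11, 15, 19]] = 0.4  # level-5 cells sum to 2 = the bound
        params = np.concatenate([d20, [np.log(0.25)]])
        assert censored_loglik(params, data, spec) == pytest.approx(np.log(0.5), abs=1e-12)

    @pytest.mark.parametrize("het", [False, True])
    def test_matches_quadrature_oracle(self, het):
        """Each observation's likelihood recomputed by 1D quadrature over the
        latent disutility."""
        rng = np.random.default_rng(42)
        data = _toy_data(rng, n=20, censor_fraction=0.25)
        spec = ModelSpec("tobit20", heteroskedastic=het, intercept_mode="free")
        k = 21
        params = np.concatenate([
            [0.05], rng.uniform(0, 0.15, 20),
            [np.log(0.3), 0.02] if het else [np.log(0.3)],
        ])
        if het:
            sigma = np.exp(np.log(0.3) + 0.02 * (data.misery - 5))
        else:
            sigma = np.full(20, 0.3)
        m = 0.05 + data.X @ params[1:21]
        expected = 0.0
        for j in range(20):
            pdf = lambda t: stats.norm.pdf(t, loc=m[j], scale=sigma[j])
            if data.censored[j]:
                mass, _ = integrate.quad(
                    pdf, CENSOR_BOUND, m[j] + 12 * sigma[j], epsabs=1e-13, epsrel=1e-12
                )
                expected += np.log(mass)
            else:
                expected += np.log(pdf(data.y[j]))
        got = censored_loglik(params, data, spec)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_invalid_sigma_rejected_not_crashed(self):
        rng = np.random.default_rng(1)
        data = _toy_data(rng)
        spec = ModelSpec("tobit20")
        params = np.concatenate([np.zeros(20), [1e4]])  # sigma overflows
        assert censored_loglik(params, data, spec) == -np.inf

    def test_analytic_gradient_matches_finite_differences(self):
        from cttolite.models import _loglik_and_grad

        rng = np.random.default_rng(3)
        data = _toy_data(rng, n=30, censor_fraction=0.3)
        for spec in (
            ModelSpec("tobit20", intercept_mode="free", heteroskedastic=True),
            ModelSpec("tobit20"),
            ModelSpec("linear20", heteroskedastic=True),
        ):
            k = len(param_names(spec))
            params = np.concatenate([rng.uniform(0.0, 0.1, k - (2 if spec.heteroskedastic else 1)),
                                     [np.log(0.4), 0.01][: (2 if spec.heteroskedastic else 1)]])
            ll, grad = _loglik_and_grad(params, data, spec)
            assert ll == pytest.approx(censored_loglik(params, data, spec), abs=1e-10)
            num = np.array([
                (censored_loglik(params + h * e, data, spec)
                 - censored_loglik(params - h * e, data, spec)) / (2 * h)
                for h, e in ((1e-6, np.eye(k)[i]) for i in range(k))
            ])
            assert np.allclose(grad, num, atol=1e-4)


class TestLinearFits:
    def test_noiseless_exact_recovery(self, lite_design, published_truth):
        truth = published_truth.scaled(0.5)  # keep every latent above -1
        responses = exact_responses(lite_design, truth)
        fit = fit_model(responses, ModelSpec("linear20"))
        est = np.array([fit.decrements20[p] for p in PARAM_NAMES])
        assert np.abs(est - truth.as_vector()).max() < 1e-6

    def test_free_intercept_absorbs_constant_shift(self, lite_design, published_truth):
        truth = published_truth.scaled(0.5)
        base = exact_responses(lite_design, truth)
        shifted = exact_responses(lite_design, truth, shift=-0.05)
        spec = ModelSpec("linear20", intercept_mode="free")
        f0, f1 = fit_model(base, spec), fit_model(shifted, spec)
        assert f1.raw_params["alpha"] - f0.raw_params["alpha"] == pytest.approx(
            0.05, abs=1e-6
        )  # -0.05 on the value scale is +0.05 disutility
        for p in PARAM_NAMES:
            assert abs(f1.decrements20[p] - f0.decrements20[p]) < 1e-3

    def test_random_intercept_variant_recovers_truth(self, study_cohort, published_truth):
        fit = fit_model(study_cohort, ct.STUDY_MODELS["model1"])
        est = np.array([fit.decrements20[p] for p in PARAM_NAMES])
        bias = np.abs(est - published_truth.as_vector())
        assert bias.mean() < 0.02
        assert fit.raw_params["tau"] == pytest.approx(0.05, abs=0.03)


class TestTobit:
    def test_equals_linear_when_nothing_censored(self, lite_design, published_truth):
        truth = published_truth.scaled(0.5)
        responses = exact_responses(lite_design, truth, respondents_per_block=3)
        lin = fit_model(responses, ModelSpec("linear20"))
        tob = fit_model(responses, ModelSpec("tobit20"))
        for p in PARAM_NAMES:
            assert abs(lin.decrements20[p] - tob.decrements20[p]) < 1e-5

    def test_censoring_correction_reduces_severe_attenuation(
        self, lite_design, published_truth
    ):
        """With real censoring at -1, the Tobit estimate of the largest
        decrement (PD5) stays closer to truth than the uncensored fit's."""
        lin_err, tob_err = [], []
        for seed in range(5):
            frame = ct.simulate_cohort(
                lite_design, 250, published_truth, ct.NoiseModel(), seed=500 + seed
            )
            lin = fit_model(frame, ModelSpec("linear20"))
            tob = fit_model(frame, ModelSpec("tobit20"))
            lin_err.append(abs(lin.decrements20["PD5"] - 0.798))
            tob_err.append(abs(tob.decrements20["PD5"] - 0.798))
        assert np.mean(tob_err) < np.mean(lin_err)

    def test_constrained_within_one_se_of_free(self, study_cohort):
        free = fit_model(study_cohort, ModelSpec("tobit20", intercept_mode="free"))
        con = fit_model(study_cohort, ModelSpec("tobit20"))
        for p in ("PD5", "MO5", "AD2"):
            assert abs(free.decrements20[p] - con.decrements20[p]) < 3 * free.se[p]

    def test_indicator_variance_covariate_option(self, lite_design, published_truth):
        frame = ct.simulate_cohort(lite_design, 150, published_truth,
                                   ct.NoiseModel(), seed=19)
        spec = ModelSpec("tobit20", heteroskedastic=True,
                         variance_covariate="indicators")
        fit = fit_model(frame, spec)
        assert fit.converged
        assert "gamma_PD5" in fit.raw_params
        # severe cells carry more residual variance than the baseline
        assert fit.raw_params["gamma_PD5"] > 0
        est = np.array([fit.decrements20[p] for p in PARAM_NAMES])
        assert np.abs(est - published_truth.as_vector()).mean() < 0.03

    def test_cluster_se_option_runs(self, lite_design, published_truth):
        frame = ct.simulate_cohort(lite_design, 60, published_truth, ct.NoiseModel(), seed=8)
        fit = fit_model(frame, ModelSpec("tobit20"), cluster_se=True)
        assert all(np.isfinite(fit.se[p]) for p in PARAM_NAMES)


class TestMultiplicative:
    def test_expansion_is_the_product(self):
        d20 = expand_multiplicative(
            np.array([0.3, 0.3, 0.3, 0.7, 0.25, 0.2, 0.4, 0.7]), "multiplicative8"
        )
        decs = dict(zip(PARAM_NAMES, d20))
        assert decs["PD3"] == pytest.approx(0.7 * 0.4)
        assert decs["PD5"] == pytest.approx(0.7)
        assert decs["MO2"] == pytest.approx(0.3 * 0.2)

    def test_noiseless_exact_recovery(self, lite_design):
        truth = multiplicative_ground_truth(
            beta=(0.3, 0.3, 0.3, 0.7, 0.25), L=(0.2, 0.4, 0.7)
        )
        responses = exact_responses(lite_design, truth)
        fit = fit_model(responses, ModelSpec("multiplicative8"))
        raw = fit.raw_params
        for name, val in zip(
            ("beta_MO", "beta_SC", "beta_UA", "beta_PD", "beta_AD", "L2", "L3", "L4"),
            (0.3, 0.3, 0.3, 0.7, 0.25, 0.2, 0.4, 0.7),
        ):
            assert raw[name] == pytest.approx(val, abs=1e-4)

    def test_nine_parameter_nests_eight(self, lite_design):
        truth = multiplicative_ground_truth(
            beta=(0.3, 0.3, 0.3, 0.7, 0.25), L=(0.2, 0.4, 0.7)
        )  # true L5 = 1
        frame = ct.simulate_cohort(
            lite_design, 150, truth.scaled(0.5),
            ct.NoiseModel(sigma_base=0.08, sigma_slope=0.02, tau=0.0), seed=77,
        )
        m8 = fit_model(frame, ModelSpec("multiplicative8"))
        m9 = fit_model(frame, ModelSpec("multiplicative9"))
        assert m9.loglik >= m8.loglik - 1e-6  # nesting
        assert m9.loglik - m8.loglik < 2.0
        assert m9.raw_params["L5"] == pytest.approx(1.0, abs=0.1)

    def test_constrained_prediction_anchors_full_health(self, lite_design, published_truth):
        frame = ct.simulate_cohort(lite_design, 80, published_truth, ct.NoiseModel(), seed=4)
        for name in ("model4_constrained", "model5"):
            fit = fit_model(frame, ct.STUDY_MODELS[name])
            assert fit.predict_value(["11111"])[0] == pytest.approx(1.0, abs=1e-12)


class TestFaceValidity:
    def test_published_coefficients_are_face_valid(self):
        fit = _dummy_fit(ct.published_decrements("analytic"))
        ok, violations = check_face_validity(fit)
        assert ok and not violations

    def test_level_inversion_detected(self):
        decs = ct.published_decrements("analytic")
        decs["MO3"] = decs["MO2"] - 0.01
        ok, violations = check_face_validity(_dummy_fit(decs))
        assert not ok and ("MO", 3) in violations

    def test_equal_adjacent_levels_allowed(self):
        decs = ct.published_decrements("analytic")
        decs["MO3"] = decs["MO2"]
        ok, _ = check_face_validity(_dummy_fit(decs))
        assert ok


def _dummy_fit(decrements):
    return FittedModel(
        spec=ModelSpec("linear20"),
        decrements20=dict(decrements),
        raw_params={},
        loglik=0.0,
        se={},
        se_decrements20={},
        n_obs=0,
        converged=True,
    )


class TestInfrastructure:
    def test_unidentified_cell_raises_named_error(self):
        frame = pd.DataFrame(
            {
                "respondent_id": [1, 1, 1],
                "state": ["11112", "11113", "55555"],
                "ctto": [0.9, 0.8, -0.5],
            }
        )
        with pytest.raises(IdentifiabilityError, match="MO2"):
            fit_model(frame, ModelSpec("linear20"))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("multiplicative8", intercept_mode="free")
        with pytest.raises(ValueError):
            ModelSpec("tobit20", random_intercept=True)
        with pytest.raises(ValueError):
            ModelSpec("nonsense")

    def test_fitted_model_json_round_trip(self, tmp_path, study_cohort):
        fit = fit_model(study_cohort.head(2000), ModelSpec("tobit20"))
        path = tmp_path / "fit.json"
        fit.to_json(path)
        again = FittedModel.from_json(path)
        assert again.spec == fit.spec
        assert again.decrements20 == fit.decrements20
        assert again.loglik == fit.loglik
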