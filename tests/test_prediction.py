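"""Competence prediction: screening, final models, fit statistics."""

import numpy as np
import pandas as pd
import pytest

from sdmnet.inference import McmcConfig
from sdmnet.prediction import (
    CompetencePredictor,
    PredictionModel,
    adjusted_r_squared,
    fit_final_model,
    fit_report,
    predict_competence,
    screen_predictors,
)
from sdmnet.simulate import StudyDesign, simulate_study


@pytest.fixture(scope="module")
def node_params_30():
    """True node parameters for 30 physicians (no MCMC needed)."""
    study = simulate_study(design=StudyDesign(n_physicians=30, seed=404))
    return study


def _linear_outcome(wide: pd.DataFrame, noise_sd: float = 0.0, seed: int = 0) -> pd.Series:
    rng = np.random.default_rng(seed)
    y = (
        20.0
        + 5.0 * (wide["activation_6"] - wide["activation_6"].mean())
        + 8.0 * (wide["outstrength_6"] - wide["outstrength_6"].mean())
    )
    return y + rng.normal(0, noise_sd, len(y))


class TestAdjustedRSquared:
    @pytest.mark.parametrize(
        "r2, expected, tol",
        [(0.510, 0.143, 5e-4), (0.621, 0.337, 5e-4), (0.611, 0.320, 1e-3)],
    )
    def test_sample_size_penalty_at_reported_scale(self, r2, expected, tol):
        # n=22 physicians, 9 predictors — the reported-model configuration;
        # the wider tolerance absorbs rounding of the printed inputs
        assert adjusted_r_squared(r2, n=22, p=9) == pytest.approx(expected, abs=tol)

    def test_undefined_when_overparameterized(self):
        with pytest.raises(ValueError):
            adjusted_r_squared(0.5, n=10, p=9)


class TestScreening:
    def test_degenerate_outcome_flagged_without_retention(self, node_params_30, fast_mcmc):
        from sdmnet.network import node_parameters_wide

        wide = node_parameters_wide(node_params_30["true_node_parameters"])
        comp = pd.DataFrame({"flat": np.full(len(wide), 42.0)}, index=wide.index)
        res = screen_predictors(wide, comp, mcmc=fast_mcmc, seed=1)
        assert res.degenerate_outcomes == ["flat"]
        assert res.retained_skills == set()

    def test_insufficient_overlap_rejected(self, node_params_30, fast_mcmc):
        from sdmnet.network import node_parameters_wide

        wide = node_parameters_wide(node_params_30["true_node_parameters"]).iloc[:5]
        comp = pd.DataFrame({"x": np.arange(5.0)}, index=wide.index)
        with pytest.raises(ValueError, match="need at least"):
            screen_predictors(wide, comp, mcmc=fast_mcmc, seed=1)

    def test_null_outcome_rarely_retains(self, node_params_30, fast_mcmc):
        # competence independent of all parameters: retention ~ type-I level
        from sdmnet.network import node_parameters_wide

        wide = node_parameters_wide(node_params_30["true_node_parameters"])
        rng = np.random.default_rng(7)
        comp = pd.DataFrame({"noise": rng.normal(20, 5, len(wide))}, index=wide.index)
        res = screen_predictors(wide, comp, mcmc=fast_mcmc, seed=2)
        assert len(res.retained_skills) <= 3


class TestFinalModel:
    def test_noise_free_linear_outcome_fits_perfectly(self, node_params_30, fast_mcmc):
        from sdmnet.network import node_parameters_wide

        wide = node_parameters_wide(node_params_30["true_node_parameters"])
        y = _linear_outcome(wide)
        model = fit_final_model(wide, y.rename("toy"), {6}, mcmc=fast_mcmc, seed=3)
        assert model.r_squared[0] > 0.98
        assert model.residual_variance[0] < 0.05 * y.var()

    def test_intercept_matches_outcome_mean_under_centring(self, node_params_30, fast_mcmc):
        from sdmnet.network import node_parameters_wide

        wide = node_parameters_wide(node_params_30["true_node_parameters"])
        y = _linear_outcome(wide, noise_sd=3.0, seed=11)
        model = fit_final_model(wide, y.rename("toy"), {1, 6}, mcmc=fast_mcmc, seed=5)
        assert model.intercept == pytest.approx(y.mean(), abs=0.15)

    def test_adjusted_r2_refused_when_p_reaches_n_minus_1(self, node_params_30, fast_mcmc):
        from sdmnet.network import node_parameters_wide

        wide = node_parameters_wide(node_params_30["true_node_parameters"]).iloc[:10]
        y = _linear_outcome(wide, noise_sd=2.0, seed=2)
        model = fit_final_model(wide, y.rename("toy"), {1, 2, 6}, mcmc=fast_mcmc, seed=6)
        assert model.n_predictors == 9
        assert model.adjusted_r_squared is None
        assert model.r_squared is not None

    def test_adjusted_never_exceeds_r_squared(self, node_params_30, fast_mcmc):
        from sdmnet.network import node_parameters_wide

        wide = node_parameters_wide(node_params_30["true_node_parameters"])
        y = _linear_outcome(wide, noise_sd=4.0, seed=8)
        model = fit_final_model(wide, y.rename("toy"), {6}, mcmc=fast_mcmc, seed=7)
        assert model.adjusted_r_squared[0] <= model.r_squared[0]

    def test_training_correlation_matches_posterior_r(self, node_params_30, fast_mcmc):
        from sdmnet.network import node_parameters_wide

        wide = node_parameters_wide(node_params_30["true_node_parameters"])
        y = _linear_outcome(wide, noise_sd=3.0, seed=21)
        model = fit_final_model(wide, y.rename("toy"), {6}, mcmc=fast_mcmc, seed=9)
        preds = predict_competence(model, wide, observed=y)
        r_emp = np.corrcoef(preds["predicted_score"], preds["observed_score"])[0, 1]
        assert r_emp == pytest.approx(model.r[0], abs=0.1)

    def test_empty_retention_rejected(self, node_params_30, fast_mcmc):
        with pytest.raises(ValueError, match="nonempty"):
            fit_final_model(
                node_params_30["true_node_parameters"],
                pd.Series(dtype=float),
                set(),
                mcmc=fast_mcmc,
            )


def _manual_model() -> PredictionModel:
    return PredictionModel(
        outcome="toy",
        retained_skills=[6],
        terms=["activation_6"],
        coef_mean=np.array([12.0, 2.0]),
        coef_lo=np.array([10.0, 1.0]),
        coef_hi=np.array([14.0, 3.0]),
        grand_means=pd.Series({"activation_6": 3.0}),
        n_observations=20,
        n_predictors=1,
        residual_variance=(1.0, 0.5, 2.0),
        model_variance=(2.0, 1.0, 4.0),
        r=(0.8, 0.6, 0.9),
        r_squared=(0.64, 0.36, 0.81),
        adjusted_r_squared=(0.6, 0.3, 0.8),
    )


class TestPredictCompetence:
    def test_parameters_at_grand_means_predict_intercept(self):
        model = _manual_model()
        wide = pd.DataFrame({"activation_6": [3.0]}, index=["pX"])
        out = predict_competence(model, wide)
        assert out["predicted_score"].iloc[0] == pytest.approx(12.0)

    def test_weighted_sum_is_exactly_linear(self):
        model = _manual_model()
        wide = pd.DataFrame({"activation_6": [4.5, 6.0]}, index=["a", "b"])
        out = predict_competence(model, wide)
        # centred parameter 1.5 with weight 2 -> 12 + 3 = 15; doubling the
        # centred parameter doubles its contribution
        assert out["predicted_score"].tolist() == pytest.approx([15.0, 18.0])

    def test_incomplete_physicians_skipped(self):
        model = _manual_model()
        wide = pd.DataFrame({"activation_6": [3.0, np.nan]}, index=["ok", "bad"])
        out = predict_competence(model, wide)
        assert out["physician_id"].tolist() == ["ok"]


class TestFitReport:
    def test_coefficient_table_shape(self, node_params_30, fast_mcmc):
        from sdmnet.network import node_parameters_wide

        wide = node_parameters_wide(node_params_30["true_node_parameters"])
        y = _linear_outcome(wide, noise_sd=3.0, seed=4)
        model = fit_final_model(wide, y.rename("toy"), {1, 6, 7}, mcmc=fast_mcmc, seed=8)
        preds = predict_competence(model, wide, observed=y)
        report = fit_report(model, preds)
        assert len(report["coefficients"]) == 1 + 3 * 3
        assert report["fit_statistics"]["n_predictors"] == 9
        assert not report["smooth"].empty

    def test_intercept_only_model_reportable(self):
        model = _manual_model()
        model.terms = []
        model.coef_mean = model.coef_mean[:1]
        model.coef_lo = model.coef_lo[:1]
        model.coef_hi = model.coef_hi[:1]
        model.grand_means = pd.Series(dtype=float)
        preds = predict_competence(model, pd.DataFrame(index=["a", "b"]))
        report = fit_report(model, preds)
        assert len(report["coefficients"]) == 1
        assert (preds["predicted_score"] == 12.0).all()

    def test_identical_observed_predicted_smooths_to_identity(self):
        model = _manual_model()
        preds = pd.DataFrame(
            {
                "physician_id": list("abcdef"),
                "outcome": "toy",
                "predicted_score": np.linspace(10, 20, 6),
                "observed_score": np.linspace(10, 20, 6),
            }
        )
        report = fit_report(model, preds)
        sm = report["smooth"]
        assert np.allclose(sm["smoothed_observed"], sm["predicted_score"], atol=1e-6)


class TestCompetencePredictorEstimator:
    def test_fit_predict_roundtrip(self, node_params_30, fast_mcmc):
        from sdmnet.network import node_parameters_wide

        wide = node_parameters_wide(node_params_30["true_node_parameters"])
        y = _linear_outcome(wide, noise_sd=1.0, seed=14).rename("toy")
        est = CompetencePredictor(screen=False, retained_skills={6}, mcmc=fast_mcmc, seed=0)
        est.fit(wide, y)
        preds = est.predict(wide)
        assert preds.shape == (len(wide),)
        assert np.corrcoef(preds, y)[0, 1] > 0.8

    def test_sklearn_param_interface(self, fast_mcmc):
        est = CompetencePredictor(mcmc=fast_mcmc)
        params = est.get_params()
        assert params["screen"] is True
        clone = CompetencePredictor(**params)
        assert clone.get_params() == params
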