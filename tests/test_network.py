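"""Skills-network estimation: centring, node models, purging, parameters."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sdmnet.inference import DicResult, McmcConfig
from sdmnet.network import (
    ITEM_COLUMNS,
    NodeModelFit,
    SkillsNetwork,
    center_predictors,
    compare_models,
    fit_node_model,
    networks_from_fits,
    node_parameters,
    node_parameters_wide,
    population_retention,
    purge_network,
)
from sdmnet.simulate import (
    StudyDesign,
    default_network_spec,
    draw_physician_parameters,
    simulate_patient_ratings,
)


class TestCenterPredictors:
    def test_constant_column_centres_to_zero(self):
        table = pd.DataFrame(
            {"physician_id": ["a", "b"], **{c: [3, 3] for c in ITEM_COLUMNS}}
        )
        centred, means = center_predictors(table)
        assert (centred[ITEM_COLUMNS] == 0).all().all()
        assert (means == 3).all()

    def test_two_point_column(self):
        table = pd.DataFrame(
            {"physician_id": ["a", "b"], **{c: [1, 5] for c in ITEM_COLUMNS}}
        )
        centred, _ = center_predictors(table)
        assert centred[ITEM_COLUMNS].iloc[0].eq(-2).all()
        assert centred[ITEM_COLUMNS].iloc[1].eq(2).all()

    def test_centred_means_vanish(self, tiny_study):
        centred, _ = center_predictors(tiny_study["patient_ratings"])
        assert np.allclose(centred[ITEM_COLUMNS].mean(), 0.0, atol=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            center_predictors(pd.DataFrame(columns=["physician_id", *ITEM_COLUMNS]))


def _network(ci_low, ci_high, weights=None):
    n = np.zeros((9, 9))
    lo = np.zeros((9, 9))
    hi = np.zeros((9, 9))
    lo[0, 1], hi[0, 1] = ci_low, ci_high
    n[0, 1] = weights if weights is not None else (ci_low + ci_high) / 2
    return SkillsNetwork(
        physician_id="p", weights=n, ci_low=lo, ci_high=hi,
        retained=np.zeros((9, 9), dtype=bool),
    )


class TestPurgeNetwork:
    @pytest.mark.parametrize(
        "interval, rule, kept",
        [
            ((0.10, 0.40), "positive", True),
            ((-0.05, 0.30), "positive", False),
            ((-0.40, -0.10), "positive", False),  # credibly negative still removed
            ((0.10, 0.40), "two-sided", True),
            ((-0.05, 0.30), "two-sided", False),
            ((-0.40, -0.10), "two-sided", True),  # excludes zero from below
        ],
    )
    def test_retention_rules(self, interval, rule, kept):
        purged = purge_network(_network(*interval), rule=rule)
        assert purged.retained[0, 1] == kept

    def test_purging_is_idempotent(self):
        net = _network(0.1, 0.4)
        once = purge_network(net)
        twice = purge_network(once)
        assert np.array_equal(once.retained, twice.retained)
        assert np.array_equal(once.weights, twice.weights)

    def test_weights_preserved_under_masking(self):
        purged = purge_network(_network(-0.05, 0.30, weights=0.12))
        assert purged.weights[0, 1] == 0.12
        assert purged.purged_weights[0, 1] == 0.0

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            purge_network(_network(0.1, 0.4), rule="bonferroni")


class TestNodeParameters:
    @staticmethod
    def _purged(weights: np.ndarray) -> SkillsNetwork:
        return SkillsNetwork(
            physician_id="p",
            weights=weights,
            ci_low=np.where(weights != 0, 0.01, -1.0),
            ci_high=np.ones((9, 9)),
            retained=weights != 0,
        )

    def test_strengths_of_small_network(self):
        W = np.zeros((9, 9))
        W[0, 1], W[0, 2] = 0.2, 0.3
        means = pd.DataFrame(
            np.full((1, 9), 3.0), index=["p"], columns=ITEM_COLUMNS
        )
        params = node_parameters(
            [self._purged(W)], activation="raw_mean", raw_item_means=means
        ).set_index("skill")
        assert params.loc[1, "outstrength"] == pytest.approx(0.5)
        assert params.loc[2, "instrength"] == pytest.approx(0.2)
        assert params.loc[3, "instrength"] == pytest.approx(0.3)

    def test_strength_sums_match_brute_force_double_loop(self, rng):
        # oracle: explicit double loop over the purged adjacency matrix
        for _ in range(100):
            W = rng.normal(0, 0.2, (9, 9)) * (rng.random((9, 9)) < 0.4)
            np.fill_diagonal(W, 0.0)
            net = self._purged(W)
            means = pd.DataFrame(np.zeros((1, 9)), index=["p"], columns=ITEM_COLUMNS)
            params = node_parameters(
                [net], activation="raw_mean", raw_item_means=means
            ).set_index("skill")
            purged = net.purged_weights
            for s in range(9):
                out_bf = sum(purged[s, k] for k in range(9))
                in_bf = sum(purged[k, s] for k in range(9))
                assert params.loc[s + 1, "outstrength"] == pytest.approx(out_bf, abs=1e-12)
                assert params.loc[s + 1, "instrength"] == pytest.approx(in_bf, abs=1e-12)
            assert params["outstrength"].sum() == pytest.approx(params["instrength"].sum())

    def test_empty_retained_mask_zeroes_strengths(self):
        net = SkillsNetwork(
            physician_id="p",
            weights=np.full((9, 9), 0.2) * (1 - np.eye(9)),
            ci_low=np.zeros((9, 9)),
            ci_high=np.zeros((9, 9)),
            retained=np.zeros((9, 9), dtype=bool),
        )
        means = pd.DataFrame(np.zeros((1, 9)), index=["p"], columns=ITEM_COLUMNS)
        params = node_parameters([net], activation="raw_mean", raw_item_means=means)
        assert (params[["outstrength", "instrength"]] == 0).all().all()


def _stub_fit(outcome_skill: int, dic: float) -> NodeModelFit:
    zeros = np.zeros(9)
    g = np.zeros((1, 8))
    return NodeModelFit(
        outcome_skill=outcome_skill,
        predictor_skills=[s for s in range(1, 10) if s != outcome_skill],
        random_effects=False,
        physician_ids=np.array(["p"]),
        pop_mean=zeros, pop_lo=zeros, pop_hi=zeros,
        phys_coef_mean=g, phys_coef_lo=g, phys_coef_hi=g,
        phys_intercept_mean=np.zeros(1),
        phys_intercept_lo=np.zeros(1),
        phys_intercept_hi=np.zeros(1),
        dic=DicResult(dic=dic, p_eff=1.0, mean_deviance=dic - 1),
        convergence=None,
        grand_mean_outcome=0.0,
        sigma2_mean=1.0,
    )


class TestCompareModels:
    def test_random_selected_when_dic_improves_by_threshold(self):
        fixed, random = _stub_fit(1, 100.0), _stub_fit(1, 96.0)
        selected, comp = compare_models(fixed, random)
        assert selected is random
        assert comp.dic_difference == pytest.approx(4.0)

    def test_fixed_retained_below_threshold(self):
        fixed, random = _stub_fit(1, 100.0), _stub_fit(1, 98.5)
        selected, comp = compare_models(fixed, random)
        assert selected is fixed
        assert comp.selected == "fixed"

    def test_mismatched_outcomes_rejected(self):
        with pytest.raises(ValueError):
            compare_models(_stub_fit(1, 100.0), _stub_fit(2, 90.0))


class TestFitNodeModel:
    def test_single_physician_fixed_effects_match_ols(self, fast_mcmc):
        spec = default_network_spec()
        design = StudyDesign(n_physicians=1, patients_per_physician=400, seed=17)
        truths = draw_physician_parameters(spec, design)
        table = simulate_patient_ratings(truths, spec, design)
        centred, gm = center_predictors(table)
        fit = fit_node_model(
            centred, outcome_skill=6, random_effects=False,
            mcmc=replace(fast_mcmc, iterations=2000, burn_in=1000), grand_means=gm,
        )
        y = centred["item_6"].to_numpy()
        X = np.column_stack(
            [np.ones(len(centred))]
            + [centred[f"item_{s}"].to_numpy() for s in fit.predictor_skills]
        )
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.pop_mean, ols, atol=0.02 * max(1, np.abs(ols).max()) + 0.01)

    def test_zero_heterogeneity_shrinks_physician_slopes(self, fast_mcmc):
        spec = replace(default_network_spec(), random_sd_intercept=0.0, random_sd_slope=0.0)
        # enough data per physician that the posterior can identify tau ~ 0
        design = StudyDesign(n_physicians=25, patients_per_physician=60, seed=19)
        truths = draw_physician_parameters(spec, design)
        table = simulate_patient_ratings(truths, spec, design)
        centred, gm = center_predictors(table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_node_model(
                centred, outcome_skill=6, random_effects=True,
                mcmc=replace(fast_mcmc, iterations=2000, burn_in=1000), grand_means=gm,
            )
        spread = fit.phys_coef_mean - fit.pop_mean[1:]
        assert np.max(np.abs(spread)) < 0.15

    def test_random_effects_need_multiple_physicians(self, fast_mcmc):
        spec = default_network_spec()
        design = StudyDesign(n_physicians=1, patients_per_physician=20, seed=3)
        truths = draw_physician_parameters(spec, design)
        table = simulate_patient_ratings(truths, spec, design)
        centred, gm = center_predictors(table)
        with pytest.raises(ValueError, match="2 physicians"):
            fit_node_model(centred, 1, random_effects=True, mcmc=fast_mcmc, grand_means=gm)


class TestEstimator:
    def test_networks_and_parameters_shape(self, fitted_network, tiny_study):
        est = fitted_network
        n_phys = tiny_study["patient_ratings"]["physician_id"].nunique()
        assert len(est.networks_) == n_phys
        assert len(est.node_parameters_) == n_phys * 9
        wide = node_parameters_wide(est.node_parameters_)
        assert wide.shape == (n_phys, 27)

    def test_activation_tracks_raw_item_means(self, fitted_network, tiny_study):
        # balanced data, centred predictors: intercept ~ adjusted item mean
        raw = tiny_study["patient_ratings"].groupby("physician_id")[ITEM_COLUMNS].mean()
        merged = fitted_network.node_parameters_.copy()
        raw_long = raw.reset_index().melt(
            id_vars="physician_id", var_name="item", value_name="raw_mean"
        )
        raw_long["skill"] = raw_long["item"].str.removeprefix("item_").astype(int)
        merged = merged.merge(raw_long[["physician_id", "skill", "raw_mean"]])
        r = np.corrcoef(merged["activation"], merged["raw_mean"])[0, 1]
        # partial pooling attenuates at 10 consultations/physician; the
        # full-scale (30x30) bound lives in the acceptance suite
        assert r >= 0.6

    def test_purged_edges_subset_of_estimated(self, fitted_network):
        for net in fitted_network.networks_:
            assert np.all(net.weights[net.retained] != 0)
            assert not net.retained.diagonal().any()

    def test_population_retention_is_shared_mask(self, fitted_network):
        mask = population_retention(fitted_network.fits_)
        assert mask.shape == (9, 9)
        assert not mask.diagonal().any()

    def test_missing_items_dropped_listwise(self, tiny_study, fast_mcmc):
        table = tiny_study["patient_ratings"].copy()
        table.loc[table.index[:3], "item_4"] = np.nan
        from sdmnet.network import _validate_patient_table

        cleaned = _validate_patient_table(table)
        assert len(cleaned) == len(table) - 3

    def test_networks_from_fits_requires_all_outcomes(self):
        with pytest.raises(ValueError, match="one fit per outcome"):
            networks_from_fits({1: _stub_fit(1, 0.0)})
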