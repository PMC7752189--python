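"""Predicting observer-rated competence from skills-network parameters.

Two stages, both Bayesian linear regressions on physician-level data:

1. *Screening*: for each observer-rated outcome, three models regress the
   outcome on all nine skills' values of one parameter type (activation,
   outstrength, instrength), grand-mean centred.  A skill is retained if at
   least one of its node parameters shows a very likely (95%) non-zero
   association with at least one outcome.
2. *Final model*: one regression per outcome with an intercept and the three
   parameter types of every retained skill.  Fit statistics (residual and
   model variance, R, R-squared, adjusted R-squared) are computed per
   posterior draw and then summarized — R, R² and adjusted R² are posterior
   means of draw-wise transforms, not transforms of posterior means.

Prediction for a new physician is the exact weighted sum of their (centred)
node parameters under the posterior-mean coefficients — no observer data
needed, which is the use case: scoring SDM competence from patient reports
alone under routine conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .inference import (
    HierarchicalLinearModel,
    McmcConfig,
    resolve_mcmc,
    run_mcmc,
)
from .network import node_parameters_wide

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningResult",
    "PredictionModel",
    "adjusted_r_squared",
    "screen_predictors",
    "fit_final_model",
    "predict_competence",
    "fit_report",
    "CompetencePredictor",
]

PARAMETER_TYPES = ("activation", "outstrength", "instrength")
N_SKILLS = 9


def adjusted_r_squared(r_squared: float, n: int, p: int) -> float:
    """Sample-size-penalized R²: 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        raise ValueError("adjusted R² undefined for p >= n - 1")
    return 1.0 - (1.0 - r_squared) * (n - 1) / (n - p - 1)


def _as_wide(node_params: pd.DataFrame) -> pd.DataFrame:
    if "skill" in node_params.columns:
        return node_parameters_wide(node_params)
    return node_params


def _align(
    wide: pd.DataFrame, competence: pd.Series
) -> tuple[pd.DataFrame, np.ndarray, pd.Index]:
    common = wide.index.intersection(competence.dropna().index)
    return wide.loc[common], competence.loc[common].to_numpy(dtype=float), common


@dataclass
class ScreeningResult:
    """Per (outcome, parameter type, skill) screening flags and the union."""

    table: pd.DataFrame  # outcome, parameter_type, skill, estimate, ci_low, ci_high, nonzero
    retained_skills: set[int]
    degenerate_outcomes: list[str] = field(default_factory=list)


def screen_predictors(
    node_params: pd.DataFrame,
    competence: pd.DataFrame,
    mcmc: McmcConfig | str | None = None,
    seed: int = 0,
) -> ScreeningResult:
    """Run the 3-models-per-outcome screening stage.

    ``competence`` is a physician-indexed frame with one column per
    observer-rated outcome.  Outcomes with (near) zero score variance are
    flagged as degenerate and contribute no retentions.
    """
    wide = _as_wide(node_params)
    config = resolve_mcmc(mcmc)
    rows = []
    retained: set[int] = set()
    degenerate: list[str] = []
    seeds = np.random.SeedSequence(seed).generate_state(
        len(competence.columns) * len(PARAMETER_TYPES)
    ) % (2**31)
    run = 0
    for outcome in competence.columns:
        X_df, y, common = _align(wide, competence[outcome])
        if len(common) < N_SKILLS + 2:
            raise ValueError(
                f"outcome {outcome}: only {len(common)} physicians with both node "
                f"parameters and competence; need at least {N_SKILLS + 2}"
            )
        if np.var(y) < 1e-12:
            degenerate.append(outcome)
            run += len(PARAMETER_TYPES)
            continue
        for ptype in PARAMETER_TYPES:
            cols = [f"{ptype}_{s}" for s in range(1, N_SKILLS + 1)]
            Xp = X_df[cols].to_numpy(dtype=float)
            Xp = Xp - Xp.mean(axis=0)
            X = np.column_stack([np.ones(len(y)), Xp])
            model = HierarchicalLinearModel(y=y, X=X, random_effects=False)
            samples = run_mcmc(model, config.with_seed(int(seeds[run])))
            run += 1
            beta = samples.pooled("beta")
            lo = np.quantile(beta, 0.025, axis=0)
            hi = np.quantile(beta, 0.975, axis=0)
            mean = beta.mean(axis=0)
            for s in range(1, N_SKILLS + 1):
                nonzero = bool(lo[s] > 0 or hi[s] < 0)
                if nonzero:
                    retained.add(s)
                rows.append(
                    {
                        "outcome": outcome,
                        "parameter_type": ptype,
                        "skill": s,
                        "estimate": mean[s],
                        "ci_low": lo[s],
                        "ci_high": hi[s],
                        "nonzero": nonzero,
                    }
                )
    return ScreeningResult(
        table=pd.DataFrame(rows), retained_skills=retained, degenerate_outcomes=degenerate
    )


@dataclass
class PredictionModel:
    """Posterior summary of one outcome's final regression."""

    outcome: str
    retained_skills: list[int]
    terms: list[str]  # feature columns, e.g. activation_6
    coef_mean: np.ndarray  # intercept first, then terms
    coef_lo: np.ndarray
    coef_hi: np.ndarray
    grand_means: pd.Series  # training means of the term columns
    n_observations: int
    n_predictors: int
    # (posterior mean, ci_low, ci_high) triples
    residual_variance: tuple[float, float, float]
    model_variance: tuple[float, float, float]
    r: tuple[float, float, float]
    r_squared: tuple[float, float, float]
    adjusted_r_squared: tuple[float, float, float] | None

    @property
    def intercept(self) -> float:
        return float(self.coef_mean[0])


def _summary(draws: np.ndarray) -> tuple[float, float, float]:
    return (
        float(draws.mean()),
        float(np.quantile(draws, 0.025)),
        float(np.quantile(draws, 0.975)),
    )


def fit_final_model(
    node_params: pd.DataFrame,
    competence: pd.Series | pd.DataFrame,
    retained_skills: set[int] | list[int],
    outcome: str | None = None,
    mcmc: McmcConfig | str | None = None,
    seed: int = 0,
) -> PredictionModel:
    """Fit the final Bayesian regression for one observer-rated outcome.

    Predictors are the three parameter types of every retained skill, centred
    at their training means.  When the predictor count p reaches n - 1 the
    model is still reported but the adjusted R² is refused (None).
    """
    if isinstance(competence, pd.DataFrame):
        if outcome is None:
            if competence.shape[1] != 1:
                raise ValueError("pass `outcome` when competence has several columns")
            outcome = competence.columns[0]
        competence = competence[outcome]
    outcome = outcome or (competence.name or "competence")
    skills = sorted(int(s) for s in retained_skills)
    if not skills:
        raise ValueError("retained_skills must be nonempty")
    wide = _as_wide(node_params)
    terms = [f"{ptype}_{s}" for s in skills for ptype in PARAMETER_TYPES]
    X_df, y, common = _align(wide, competence)
    n, p = len(common), len(terms)
    if n < 3:
        raise ValueError("need at least 3 physicians with both data sources")
    grand_means = X_df[terms].mean()
    Xc = (X_df[terms] - grand_means).to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), Xc])

    model = HierarchicalLinearModel(y=y, X=X, random_effects=False)
    samples = run_mcmc(model, resolve_mcmc(mcmc, seed=seed))
    beta = samples.pooled("beta")
    sigma2 = samples.pooled("sigma2")

    linpred = beta @ X.T  # (draws, n)
    model_var = linpred.var(axis=1, ddof=1)
    r2 = model_var / (model_var + sigma2)
    r = np.sqrt(r2)
    overparam = n - p - 1 <= 0
    if overparam:
        logger.warning(
            "%s: p=%d >= n-1=%d — overparameterized; adjusted R² refused", outcome, p, n - 1
        )
        adj = None
    else:
        adj = _summary(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))
    return PredictionModel(
        outcome=str(outcome),
        retained_skills=skills,
        terms=terms,
        coef_mean=beta.mean(axis=0),
        coef_lo=np.quantile(beta, 0.025, axis=0),
        coef_hi=np.quantile(beta, 0.975, axis=0),
        grand_means=grand_means,
        n_observations=n,
        n_predictors=p,
        residual_variance=_summary(sigma2),
        model_variance=_summary(model_var),
        r=_summary(r),
        r_squared=_summary(r2),
        adjusted_r_squared=adj,
    )


def predict_competence(
    model: PredictionModel,
    node_params: pd.DataFrame,
    observed: pd.Series | None = None,
) -> pd.DataFrame:
    """Weighted-sum competence predictions for every physician with complete
    node parameters (no observer data required).  Exact linear algebra under
    the posterior-mean coefficients; physicians with missing parameters are
    skipped with a log entry."""
    wide = _as_wide(node_params)
    missing_cols = [t for t in model.terms if t not in wide.columns]
    if missing_cols:
        raise ValueError(f"node parameters lack required columns: {missing_cols}")
    vals = wide[model.terms]
    complete = ~vals.isna().any(axis=1)
    skipped = list(wide.index[~complete])
    if skipped:
        logger.info("%s: skipped physicians with incomplete parameters: %s", model.outcome, skipped)
    centred = vals.loc[complete] - model.grand_means
    pred = model.coef_mean[0] + centred.to_numpy(dtype=float) @ model.coef_mean[1:]
    out = pd.DataFrame(
        {
            "physician_id": centred.index,
            "outcome": model.outcome,
            "predicted_score": pred,
        }
    )
    if observed is not None:
        out["observed_score"] = observed.reindex(centred.index).to_numpy()
    return out


def fit_report(model: PredictionModel, predictions: pd.DataFrame) -> dict:
    """Coefficient table, fit statistics and observed-vs-predicted scatter
    data (with a loess smoothing curve when observations are present)."""
    rows = [
        {
            "outcome": model.outcome,
            "skill": None,
            "parameter_type": "intercept",
            "estimate": model.coef_mean[0],
            "ci_low": model.coef_lo[0],
            "ci_high": model.coef_hi[0],
        }
    ]
    for i, term in enumerate(model.terms, start=1):
        ptype, skill = term.rsplit("_", 1)
        rows.append(
            {
                "outcome": model.outcome,
                "skill": int(skill),
                "parameter_type": ptype,
                "estimate": model.coef_mean[i],
                "ci_low": model.coef_lo[i],
                "ci_high": model.coef_hi[i],
            }
        )
    coef_table = pd.DataFrame(rows)
    stats = {
        "outcome": model.outcome,
        "n_observations": model.n_observations,
        "n_predictors": model.n_predictors,
        "residual_variance": model.residual_variance,
        "model_variance": model.model_variance,
        "r": model.r,
        "r_squared": model.r_squared,
        "adjusted_r_squared": model.adjusted_r_squared,
    }
    scatter = predictions.copy()
    if "observed_score" in scatter.columns and scatter["observed_score"].notna().sum() >= 3:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        obs = scatter.dropna(subset=["observed_score"])
        smooth = lowess(
            obs["observed_score"].to_numpy(),
            obs["predicted_score"].to_numpy(),
            frac=0.8,
            return_sorted=True,
        )
        smooth_df = pd.DataFrame(smooth, columns=["predicted_score", "smoothed_observed"])
    else:
        smooth_df = pd.DataFrame(columns=["predicted_score", "smoothed_observed"])
    return {"coefficients": coef_table, "fit_statistics": stats, "scatter": scatter, "smooth": smooth_df}


class CompetencePredictor(BaseEstimator, RegressorMixin):
    """Regressor mapping node parameters to observer-rated competence.

    ``fit(X, y)`` takes a physician-indexed wide node-parameter frame (27
    columns, as produced by ``SkillsNetworkEstimator.fit_transform``) and a
    competence series aligned on physician.  With ``screen=True`` the
    three-model screening stage selects the skills first; a precomputed
    ``retained_skills`` set skips screening (used when screening should pool
    several outcomes).

    Fitted attributes: ``screening_`` (if run), ``model_``, ``coef_``,
    ``intercept_``.
    """

    def __init__(
        self,
        outcome: str | None = None,
        screen: bool = True,
        retained_skills: set[int] | None = None,
        mcmc: McmcConfig | str | None = None,
        seed: int = 0,
    ):
        self.outcome = outcome
        self.screen = screen
        self.retained_skills = retained_skills
        self.mcmc = mcmc
        self.seed = seed

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "CompetencePredictor":
        wide = _as_wide(X)
        y = pd.Series(np.asarray(y, dtype=float), index=wide.index) if not isinstance(y, pd.Series) else y
        outcome = self.outcome or (y.name or "competence")
        retained = self.retained_skills
        if retained is None:
            if self.screen:
                self.screening_ = screen_predictors(
                    wide, y.to_frame(outcome), mcmc=self.mcmc, seed=self.seed
                )
                retained = self.screening_.retained_skills
                if not retained:
                    logger.warning("%s: screening retained no skills; using all 9", outcome)
                    retained = set(range(1, N_SKILLS + 1))
            else:
                retained = set(range(1, N_SKILLS + 1))
        self.model_ = fit_final_model(
            wide, y, retained, outcome=outcome, mcmc=self.mcmc, seed=self.seed + 1
        )
        self.coef_ = self.model_.coef_mean[1:]
        self.intercept_ = self.model_.intercept
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("predictor is not fitted")
        preds = predict_competence(self.model_, _as_wide(X))
        return preds["predicted_score"].to_numpy()
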