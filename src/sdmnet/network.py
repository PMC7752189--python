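"""Per-physician skills networks from patient ratings.

Each of the 9 SDM-Q-9 items (skills) is regressed on the other 8 in a
Bayesian hierarchical linear model over all consultations of all physicians,
with the intercept and every slope receiving physician-level random
deviations (random-slope models) or being fixed across physicians; the
deviance information criterion decides between the two per outcome skill.
The physician-specific coefficients assemble into a directed, weighted
9-node network per physician, which is purged of edges whose 95% credible
interval does not exclude zero, and summarized by three node parameters:

* activation  -- the physician-specific model intercept (predictors are
  grand-mean centred, so this is the physician's adjusted item level on the
  0-5 scale); a raw item mean variant is available,
* outstrength -- sum of retained outgoing edge weights,
* instrength  -- sum of retained incoming edge weights.

Partial pooling is intrinsic: physician estimates borrow strength from all
other physicians' data through the group-level Normal prior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .inference import (
    ConvergenceReport,
    DicResult,
    HierarchicalLinearModel,
    McmcConfig,
    credible_interval,
    dic,
    gelman_rubin,
    resolve_mcmc,
    run_mcmc,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NodeModelFit",
    "SkillsNetwork",
    "ModelComparison",
    "center_predictors",
    "fit_node_model",
    "compare_models",
    "networks_from_fits",
    "purge_network",
    "population_retention",
    "node_parameters",
    "SkillsNetworkEstimator",
]

N_SKILLS = 9
ITEM_COLUMNS = [f"item_{i}" for i in range(1, N_SKILLS + 1)]


def _validate_patient_table(table: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in ["physician_id", *ITEM_COLUMNS] if c not in table.columns]
    if missing_cols:
        raise ValueError(f"patient rating table lacks columns: {missing_cols}")
    items = table[ITEM_COLUMNS].to_numpy(dtype=float)
    complete = ~np.isnan(items).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d consultations with missing items (listwise)", n_dropped)
    return table.loc[complete].reset_index(drop=True)


def center_predictors(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Grand-mean centre every item column over all consultations.

    Returns the centred table and the grand means (needed to put intercepts
    back on the 0-5 item scale and for prediction on new data).
    """
    if table.empty:
        raise ValueError("patient rating table is empty")
    centred = table.copy()
    grand_means = table[ITEM_COLUMNS].mean()
    centred[ITEM_COLUMNS] = table[ITEM_COLUMNS] - grand_means
    return centred, grand_means


@dataclass
class NodeModelFit:
    """Posterior summary of one node-wise hierarchical regression."""

    outcome_skill: int  # 1-9
    predictor_skills: list[int]  # the other eight, in order
    random_effects: bool
    physician_ids: np.ndarray
    # population-level: index 0 = intercept, 1.. = predictors
    pop_mean: np.ndarray
    pop_lo: np.ndarray
    pop_hi: np.ndarray
    # physician-specific coefficients (population + deviation), (G, 8)
    phys_coef_mean: np.ndarray
    phys_coef_lo: np.ndarray
    phys_coef_hi: np.ndarray
    # physician-specific intercepts on the outcome item scale, (G,)
    phys_intercept_mean: np.ndarray
    phys_intercept_lo: np.ndarray
    phys_intercept_hi: np.ndarray
    dic: DicResult
    convergence: ConvergenceReport
    grand_mean_outcome: float
    sigma2_mean: float


def fit_node_model(
    centred: pd.DataFrame,
    outcome_skill: int,
    random_effects: bool,
    mcmc: McmcConfig | str | None = None,
    seed: int | None = None,
    grand_means: pd.Series | None = None,
    coef_prior_sd: float = 100.0,
) -> NodeModelFit:
    """Fit one outcome skill's hierarchical regression on the centred table.

    ``centred`` must already be grand-mean centred (see
    :func:`center_predictors`); pass the accompanying ``grand_means`` so the
    physician intercepts are reported on the raw 0-5 item scale.
    Non-convergence (split R-hat above threshold) is signalled as a warning
    carrying the diagnostics; the report is attached to the returned fit.
    """
    if not 1 <= outcome_skill <= N_SKILLS:
        raise ValueError("outcome_skill must be in 1..9")
    config = resolve_mcmc(mcmc, seed=seed)
    predictors = [s for s in range(1, N_SKILLS + 1) if s != outcome_skill]
    y = centred[f"item_{outcome_skill}"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(centred))] + [centred[f"item_{s}"].to_numpy(dtype=float) for s in predictors]
    )
    groups = centred["physician_id"].to_numpy()
    if random_effects and len(np.unique(groups)) < 2:
        raise ValueError("random-effects node models require at least 2 physicians")

    model = HierarchicalLinearModel(
        y=y, X=X, groups=groups, random_effects=random_effects, coef_prior_sd=coef_prior_sd
    )
    samples = run_mcmc(model, config)
    report = gelman_rubin(samples, rhat_threshold=config.rhat_threshold)
    if not report.passed:
        warnings.warn(
            f"node model for skill {outcome_skill} "
            f"({'random' if random_effects else 'fixed'}): max split R-hat "
            f"{report.max_rhat:.3f} exceeds {config.rhat_threshold}",
            RuntimeWarning,
            stacklevel=2,
        )

    beta = samples.pooled("beta")  # (draws, 9)
    pop_lo, pop_hi = credible_interval(samples, "beta")
    G = model.n_groups
    if random_effects:
        b = samples.pooled("b")  # (draws, G, 9)
        phys = beta[:, None, :] + b
    else:
        phys = np.repeat(beta[:, None, :], G, axis=1)
    coef_draws = phys[:, :, 1:]
    int_draws = phys[:, :, 0]
    gm_out = float(grand_means[f"item_{outcome_skill}"]) if grand_means is not None else 0.0

    def _ci(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return np.quantile(arr, 0.025, axis=0), np.quantile(arr, 0.975, axis=0)

    coef_lo, coef_hi = _ci(coef_draws)
    int_lo, int_hi = _ci(int_draws)
    return NodeModelFit(
        outcome_skill=outcome_skill,
        predictor_skills=predictors,
        random_effects=random_effects,
        physician_ids=model.group_labels,
        pop_mean=beta.mean(axis=0),
        pop_lo=np.atleast_1d(pop_lo),
        pop_hi=np.atleast_1d(pop_hi),
        phys_coef_mean=coef_draws.mean(axis=0),
        phys_coef_lo=coef_lo,
        phys_coef_hi=coef_hi,
        phys_intercept_mean=int_draws.mean(axis=0) + gm_out,
        phys_intercept_lo=int_lo + gm_out,
        phys_intercept_hi=int_hi + gm_out,
        dic=dic(samples, model),
        convergence=report,
        grand_mean_outcome=gm_out,
        sigma2_mean=float(samples.posterior_mean("sigma2")),
    )


@dataclass(frozen=True)
class ModelComparison:
    """DIC-based choice between fixed and random-slope node models."""

    outcome_skill: int
    dic_fixed: float
    dic_random: float
    threshold: float
    selected: str  # "fixed" or "random"

    @property
    def dic_difference(self) -> float:
        """DIC(fixed) - DIC(random); positive favours the random model."""
        return self.dic_fixed - self.dic_random


def compare_models(
    fit_fixed: NodeModelFit, fit_random: NodeModelFit, threshold: float = 3.0
) -> tuple[NodeModelFit, ModelComparison]:
    """Select the random-effects fit iff its DIC undercuts the fixed fit by at
    least ``threshold`` points (differences below that are not relevant)."""
    if fit_fixed.outcome_skill != fit_random.outcome_skill:
        raise ValueError("fits must concern the same outcome skill")
    d_fixed, d_random = fit_fixed.dic.dic, fit_random.dic.dic
    use_random = d_random <= d_fixed - threshold
    comparison = ModelComparison(
        outcome_skill=fit_fixed.outcome_skill,
        dic_fixed=d_fixed,
        dic_random=d_random,
        threshold=threshold,
        selected="random" if use_random else "fixed",
    )
    return (fit_random if use_random else fit_fixed), comparison


@dataclass
class SkillsNetwork:
    """Directed weighted 9-node network of one physician.

    ``weights[j, k]`` is the physician-specific coefficient of skill j+1
    predicting skill k+1; the diagonal is structurally zero.  ``retained``
    masks edges surviving the purge; all estimated weights are preserved in
    ``weights``.
    """

    physician_id: str
    weights: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    retained: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.weights, self.ci_low, self.ci_high, self.retained):
            if arr.shape != (N_SKILLS, N_SKILLS):
                raise ValueError("network matrices must be 9x9")
        if np.any(np.diag(self.weights) != 0) or np.any(np.diag(self.retained)):
            raise ValueError("diagonal must be structurally zero / not retained")

    @property
    def purged_weights(self) -> np.ndarray:
        return np.where(self.retained, self.weights, 0.0)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for j in range(N_SKILLS):
            for k in range(N_SKILLS):
                if j == k:
                    continue
                rows.append(
                    {
                        "physician_id": self.physician_id,
                        "source_skill": j + 1,
                        "target_skill": k + 1,
                        "weight": self.weights[j, k],
                        "ci_low": self.ci_low[j, k],
                        "ci_high": self.ci_high[j, k],
                        "retained": bool(self.retained[j, k]),
                    }
                )
        return pd.DataFrame(rows)


def networks_from_fits(fits: dict[int, NodeModelFit]) -> list[SkillsNetwork]:
    """Assemble per-physician adjacency matrices from the 9 node-wise fits.

    Edges start unretained; apply :func:`purge_network` to set the mask.
    """
    if sorted(fits) != list(range(1, N_SKILLS + 1)):
        raise ValueError("need one fit per outcome skill 1..9")
    ids = fits[1].physician_ids
    for fit in fits.values():
        if not np.array_equal(fit.physician_ids, ids):
            raise ValueError("fits disagree on the physician set")
    networks = []
    for g, pid in enumerate(ids):
        W = np.zeros((N_SKILLS, N_SKILLS))
        lo = np.zeros((N_SKILLS, N_SKILLS))
        hi = np.zeros((N_SKILLS, N_SKILLS))
        for k, fit in fits.items():
            for idx, j in enumerate(fit.predictor_skills):
                W[j - 1, k - 1] = fit.phys_coef_mean[g, idx]
                lo[j - 1, k - 1] = fit.phys_coef_lo[g, idx]
                hi[j - 1, k - 1] = fit.phys_coef_hi[g, idx]
        networks.append(
            SkillsNetwork(
                physician_id=str(pid),
                weights=W,
                ci_low=lo,
                ci_high=hi,
                retained=np.zeros((N_SKILLS, N_SKILLS), dtype=bool),
            )
        )
    return networks


def purge_network(network: SkillsNetwork, rule: str = "positive") -> SkillsNetwork:
    """Remove possibly spurious edges by credible-interval criterion.

    rule="positive" (default): retain an edge iff its 95% credible interval
    lies entirely above zero — edge weights not credibly *higher* than zero
    are removed.  rule="two-sided": retain iff the interval excludes zero on
    either side.  Purging is idempotent; weights are masked, never erased.
    """
    if rule == "positive":
        retained = network.ci_low > 0
    elif rule == "two-sided":
        retained = (network.ci_low > 0) | (network.ci_high < 0)
    else:
        raise ValueError("rule must be 'positive' or 'two-sided'")
    np.fill_diagonal(retained, False)
    return replace(network, retained=retained)


def population_retention(fits: dict[int, NodeModelFit], rule: str = "positive") -> np.ndarray:
    """Edge retention decided at the population level: one mask shared by all
    physicians, from the population coefficients' credible intervals.  This
    keeps the retained edge set consistent across physicians (no physician-
    to-physician selection flicker), at the cost of not letting individual
    networks drop edges."""
    mask = np.zeros((N_SKILLS, N_SKILLS), dtype=bool)
    for k, fit in fits.items():
        for idx, j in enumerate(fit.predictor_skills):
            lo, hi = fit.pop_lo[idx + 1], fit.pop_hi[idx + 1]
            if rule == "positive":
                mask[j - 1, k - 1] = lo > 0
            elif rule == "two-sided":
                mask[j - 1, k - 1] = lo > 0 or hi < 0
            else:
                raise ValueError("rule must be 'positive' or 'two-sided'")
    return mask


def node_parameters(
    networks: list[SkillsNetwork],
    fits: dict[int, NodeModelFit] | None = None,
    activation: str = "intercept",
    raw_item_means: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per physician x skill: activation, outstrength, instrength.

    activation="intercept" reads the physician-specific model intercept from
    the node fits (0-5 scale, adjusted for the centred predictors);
    activation="raw_mean" uses the physician's raw item mean, supplied as
    ``raw_item_means`` (physician_id-indexed frame with item_1..item_9).
    Strengths sum retained edge weights only.
    """
    if activation == "intercept":
        if fits is None:
            raise ValueError("activation='intercept' requires the node fits")
    elif activation == "raw_mean":
        if raw_item_means is None:
            raise ValueError("activation='raw_mean' requires raw_item_means")
    else:
        raise ValueError("activation must be 'intercept' or 'raw_mean'")

    rows = []
    for net in networks:
        purged = net.purged_weights
        out = purged.sum(axis=1)
        inn = purged.sum(axis=0)
        for s in range(N_SKILLS):
            if activation == "intercept":
                fit = fits[s + 1]
                idx = np.flatnonzero(fit.physician_ids == net.physician_id)
                if idx.size == 0:
                    raise KeyError(f"physician {net.physician_id} absent from node fits")
                act = float(fit.phys_intercept_mean[idx[0]])
            else:
                act = float(raw_item_means.loc[net.physician_id, f"item_{s + 1}"])
            rows.append(
                {
                    "physician_id": net.physician_id,
                    "skill": s + 1,
                    "activation": act,
                    "outstrength": float(out[s]),
                    "instrength": float(inn[s]),
                }
            )
    return pd.DataFrame(rows)


class SkillsNetworkEstimator(BaseEstimator):
    """Estimate per-physician skills networks from a patient rating table.

    Parameters
    ----------
    model_selection:
        "dic" fits fixed and random-slope models per outcome and keeps the
        one the DIC prefers; "random" / "fixed" skip the comparison.
    purge_rule:
        "positive" (retain edges credibly above zero) or "two-sided".
    purge_level:
        "physician" tests each physician-specific coefficient's interval;
        "population" shares one retention mask from the population
        coefficients across all physicians.
    activation:
        "intercept" (physician-specific model intercept) or "raw_mean".
    mcmc:
        An :class:`McmcConfig`, a preset name ("desk", "paper"), or None.
    seed:
        Root seed; per-skill fits use deterministic child seeds.

    Fitted attributes: ``grand_means_``, ``fits_``, ``comparisons_``,
    ``networks_``, ``node_parameters_``.
    """

    def __init__(
        self,
        model_selection: str = "dic",
        purge_rule: str = "positive",
        purge_level: str = "physician",
        activation: str = "intercept",
        mcmc: McmcConfig | str | None = None,
        seed: int = 0,
        dic_threshold: float = 3.0,
    ):
        self.model_selection = model_selection
        self.purge_rule = purge_rule
        self.purge_level = purge_level
        self.activation = activation
        self.mcmc = mcmc
        self.seed = seed
        self.dic_threshold = dic_threshold

    def fit(self, X: pd.DataFrame, y=None) -> "SkillsNetworkEstimator":
        if self.model_selection not in ("dic", "random", "fixed"):
            raise ValueError("model_selection must be 'dic', 'random' or 'fixed'")
        table = _validate_patient_table(X)
        centred, self.grand_means_ = center_predictors(table)
        base = resolve_mcmc(self.mcmc)
        seeds = np.random.SeedSequence(self.seed).generate_state(2 * N_SKILLS) % (2**31)

        self.fits_: dict[int, NodeModelFit] = {}
        self.comparisons_: dict[int, ModelComparison] = {}
        for skill in range(1, N_SKILLS + 1):
            kwargs = dict(
                centred=centred, outcome_skill=skill, mcmc=base, grand_means=self.grand_means_
            )
            if self.model_selection == "dic":
                fixed = fit_node_model(
                    random_effects=False, seed=int(seeds[2 * (skill - 1)]), **kwargs
                )
                random = fit_node_model(
                    random_effects=True, seed=int(seeds[2 * (skill - 1) + 1]), **kwargs
                )
                selected, comparison = compare_models(fixed, random, self.dic_threshold)
                self.comparisons_[skill] = comparison
            else:
                selected = fit_node_model(
                    random_effects=self.model_selection == "random",
                    seed=int(seeds[2 * (skill - 1) + 1]),
                    **kwargs,
                )
            self.fits_[skill] = selected

        raw_networks = networks_from_fits(self.fits_)
        if self.purge_level == "physician":
            self.networks_ = [purge_network(net, self.purge_rule) for net in raw_networks]
        elif self.purge_level == "population":
            mask = population_retention(self.fits_, self.purge_rule)
            self.networks_ = [replace(net, retained=mask.copy()) for net in raw_networks]
        else:
            raise ValueError("purge_level must be 'physician' or 'population'")
        raw_means = table.groupby("physician_id")[ITEM_COLUMNS].mean()
        self.node_parameters_ = node_parameters(
            self.networks_,
            fits=self.fits_,
            activation=self.activation,
            raw_item_means=raw_means,
        )
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        """Fit and return the wide physician x (parameter, skill) table used
        as the feature matrix for competence prediction."""
        self.fit(X)
        return node_parameters_wide(self.node_parameters_)


def node_parameters_wide(node_params: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long node-parameter table to physician x 27 columns
    (activation_1..9, outstrength_1..9, instrength_1..9)."""
    wide = node_params.pivot(
        index="physician_id", columns="skill", values=["activation", "outstrength", "instrength"]
    )
    wide.columns = [f"{param}_{skill}" for param, skill in wide.columns]
    order = [
        f"{param}_{s}"
        for param in ("activation", "outstrength", "instrength")
        for s in range(1, N_SKILLS + 1)
    ]
    return wide[order].sort_index()
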