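"""Observer-rated competence scoring, variance decomposition and reliability.

Trained observers code audio-recorded consultations with item-level
instruments (OPTION-12, OPTION-5, the "Invest in the End" subscale of the
Four Habits Coding Scheme).  This module turns those item scores into
physician-level competence on a 0-100 scale:

1. composite per (consultation, rater): unweighted item mean (formative
   measurement model);
2. rescale to 0-100;
3. average over raters within consultation, then over consultations within
   physician.

Quality checks: a nested variance decomposition (physician / consultation /
residual) yielding the physician-level intracluster correlation, and an
inter-rater reliability coefficient for the physician-level mean of c
consultations rated by k raters, in fixed-rater and random-rater variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .inference import CrossedRandomInterceptsModel, McmcConfig, resolve_mcmc, run_mcmc

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSpec",
    "DEFAULT_INSTRUMENTS",
    "CompetenceScore",
    "VarianceDecomposition",
    "ReliabilityResult",
    "composite_score",
    "rescale_to_0_100",
    "rescaled_composites",
    "physician_competence",
    "competence_table",
    "variance_decomposition",
    "interrater_reliability",
    "ObserverCompetenceScorer",
]


@dataclass(frozen=True)
class InstrumentSpec:
    """Item count and item score range of an observer-rated instrument."""

    name: str
    n_items: int
    item_min: int
    item_max: int

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.item_min >= self.item_max:
            raise ValueError("item_min must be < item_max")

    @property
    def item_columns(self) -> list[str]:
        return [f"item_{i}" for i in range(1, self.n_items + 1)]


# Editable defaults; the instruments' published item counts and ranges.
DEFAULT_INSTRUMENTS: dict[str, InstrumentSpec] = {
    "OPTION-12": InstrumentSpec("OPTION-12", n_items=12, item_min=0, item_max=4),
    "OPTION-5": InstrumentSpec("OPTION-5", n_items=5, item_min=0, item_max=4),
    "4HCS-InvestInTheEnd": InstrumentSpec("4HCS-InvestInTheEnd", n_items=10, item_min=1, item_max=5),
}


@dataclass(frozen=True)
class CompetenceScore:
    physician_id: str
    instrument: str
    score: float  # 0-100
    n_consultations: int
    n_raters: int


def composite_score(items, spec: InstrumentSpec) -> float:
    """Unweighted mean of a complete item vector (formative model)."""
    arr = np.asarray(items, dtype=float)
    if arr.shape != (spec.n_items,):
        raise ValueError(f"{spec.name} expects {spec.n_items} items, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError("incomplete rating record (missing item)")
    if arr.min() < spec.item_min or arr.max() > spec.item_max:
        raise ValueError(
            f"item scores outside [{spec.item_min}, {spec.item_max}] for {spec.name}"
        )
    return float(arr.mean())


def rescale_to_0_100(raw: float, spec: InstrumentSpec) -> float:
    """Linear transform of a raw composite onto the 0-100 competence scale."""
    if raw < spec.item_min or raw > spec.item_max:
        raise ValueError(f"raw score {raw} outside [{spec.item_min}, {spec.item_max}]")
    return 100.0 * (raw - spec.item_min) / (spec.item_max - spec.item_min)


def rescaled_composites(table: pd.DataFrame, spec: InstrumentSpec) -> pd.DataFrame:
    """Per-(consultation, rater) rescaled composite scores for one instrument.

    Records with any missing item are dropped listwise; the number dropped is
    logged.  Returns columns physician_id, consultation_id, rater_id, score.
    """
    sub = table[table["instrument"] == spec.name]
    cols = spec.item_columns
    missing = [c for c in cols if c not in sub.columns]
    if missing:
        raise ValueError(f"table lacks item columns for {spec.name}: {missing}")
    items = sub[cols].to_numpy(dtype=float)
    complete = ~np.isnan(items).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("%s: dropped %d incomplete rating records", spec.name, n_dropped)
    sub = sub.loc[complete]
    items = items[complete]
    if items.size and (items.min() < spec.item_min or items.max() > spec.item_max):
        raise ValueError(f"item scores outside declared range for {spec.name}")
    raw = items.mean(axis=1)
    score = 100.0 * (raw - spec.item_min) / (spec.item_max - spec.item_min)
    return pd.DataFrame(
        {
            "physician_id": sub["physician_id"].to_numpy(),
            "consultation_id": sub["consultation_id"].to_numpy(),
            "rater_id": sub["rater_id"].to_numpy(),
            "score": score,
        }
    )


def physician_competence(table: pd.DataFrame, spec: InstrumentSpec) -> list[CompetenceScore]:
    """Physician-level competence: rater mean per consultation, then
    consultation mean per physician.  Physicians without observer data are
    omitted, not imputed."""
    comps = rescaled_composites(table, spec)
    if comps.empty:
        return []
    per_cons = (
        comps.groupby(["physician_id", "consultation_id"], sort=True)["score"].mean().reset_index()
    )
    out = []
    for pid, grp in per_cons.groupby("physician_id", sort=True):
        n_raters = int(
            comps[comps["physician_id"] == pid].groupby("consultation_id")["rater_id"].nunique().max()
        )
        out.append(
            CompetenceScore(
                physician_id=str(pid),
                instrument=spec.name,
                score=float(grp["score"].mean()),
                n_consultations=len(grp),
                n_raters=n_raters,
            )
        )
    return out


def competence_table(
    table: pd.DataFrame, instruments: dict[str, InstrumentSpec] | None = None
) -> pd.DataFrame:
    """Wide physician x instrument table of 0-100 competence scores."""
    instruments = instruments or DEFAULT_INSTRUMENTS
    frames = []
    for spec in instruments.values():
        scores = physician_competence(table, spec)
        if scores:
            frames.append(
                pd.DataFrame(
                    {
                        "physician_id": [s.physician_id for s in scores],
                        spec.name: [s.score for s in scores],
                    }
                ).set_index("physician_id")
            )
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, axis=1).sort_index()


@dataclass
class VarianceDecomposition:
    """REML variance components of rescaled composites and the physician ICC."""

    instrument: str
    var_physician: float
    var_consultation: float
    var_residual: float
    icc: float
    n_physicians: int
    n_records: int
    zero_variance: bool = False

    @property
    def total(self) -> float:
        return self.var_physician + self.var_consultation + self.var_residual


def variance_decomposition(table: pd.DataFrame, spec: InstrumentSpec) -> VarianceDecomposition:
    """Nested variance decomposition physician / consultation / residual.

    Fitted by restricted maximum likelihood on the per-rater rescaled
    composites; negative component estimates are truncated at zero (the REML
    optimizer already constrains them).  The residual level absorbs rater
    disagreement within consultations.
    """
    comps = rescaled_composites(table, spec)
    n_phys = comps["physician_id"].nunique()
    if n_phys < 2:
        raise ValueError("variance decomposition needs at least 2 physicians")
    if comps["score"].var(ddof=0) < 1e-12:
        return VarianceDecomposition(
            instrument=spec.name,
            var_physician=0.0,
            var_consultation=0.0,
            var_residual=0.0,
            icc=0.0,
            n_physicians=n_phys,
            n_records=len(comps),
            zero_variance=True,
        )
    import statsmodels.formula.api as smf

    df = comps.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "score ~ 1",
            data=df,
            groups="physician_id",
            re_formula="1",
            vc_formula={"consultation": "0 + C(consultation_id)"},
        )
        fit = model.fit(reml=True)
    var_physician = max(float(fit.cov_re.iloc[0, 0]), 0.0)
    var_consultation = max(float(np.asarray(fit.vcomp).ravel()[0]), 0.0)
    var_residual = max(float(fit.scale), 0.0)
    total = var_physician + var_consultation + var_residual
    icc = var_physician / total if total > 0 else 0.0
    return VarianceDecomposition(
        instrument=spec.name,
        var_physician=var_physician,
        var_consultation=var_consultation,
        var_residual=var_residual,
        icc=icc,
        n_physicians=n_phys,
        n_records=len(comps),
    )


@dataclass
class ReliabilityResult:
    """Inter-rater reliability of the physician-level mean score.

    With components (P = physician, C = consultation within physician,
    R = rater, E = residual) and a design of c consultations rated by k
    raters each, the reliability of the physician mean is

        P / (P + C/c + (R * [random-rater] + E) / (c * k))

    The fixed-rater variant conditions on the rater panel and drops R from
    the error term; the random-rater variant generalizes over raters.
    """

    instrument: str
    var_physician: float
    var_consultation: float
    var_rater: float
    var_residual: float
    c: float
    k: float
    reliability_random: float
    reliability_fixed: float


def _reliability(P: float, C: float, R: float, E: float, c: float, k: float, random_rater: bool) -> float:
    denom = P + C / c + ((R if random_rater else 0.0) + E) / (c * k)
    return P / denom if denom > 0 else 0.0


def interrater_reliability(
    table: pd.DataFrame,
    spec: InstrumentSpec,
    mcmc: McmcConfig | str | None = None,
    seed: int | None = None,
) -> ReliabilityResult:
    """Physician-level inter-rater reliability from a three-level model.

    Variance components (physician, consultation-within-physician, rater,
    residual) are estimated from a crossed random-intercepts model on the
    rescaled composites — the rater factor is crossed with physicians because
    raters form a shared pool — sampled with the package's Gibbs engine and
    summarized by posterior means.  Both fixed-rater and random-rater
    reliability variants are reported.
    """
    comps = rescaled_composites(table, spec)
    raters_per_cons = comps.groupby(["physician_id", "consultation_id"])["rater_id"].nunique()
    if (raters_per_cons < 2).all():
        raise ValueError("inter-rater reliability needs >= 2 raters for some consultations")
    cons_code = comps["physician_id"].astype(str) + ":" + comps["consultation_id"].astype(str)
    model = CrossedRandomInterceptsModel(
        y=comps["score"].to_numpy(),
        factors={
            "physician": comps["physician_id"].to_numpy(),
            "consultation": cons_code.to_numpy(),
            "rater": comps["rater_id"].to_numpy(),
        },
    )
    samples = run_mcmc(model, resolve_mcmc(mcmc, seed=seed))
    P = float(samples.posterior_mean("var_physician"))
    C = float(samples.posterior_mean("var_consultation"))
    R = float(samples.posterior_mean("var_rater"))
    E = float(samples.posterior_mean("sigma2"))
    c = float(comps.groupby("physician_id")["consultation_id"].nunique().mean())
    k = float(raters_per_cons.mean())
    return ReliabilityResult(
        instrument=spec.name,
        var_physician=P,
        var_consultation=C,
        var_rater=R,
        var_residual=E,
        c=c,
        k=k,
        reliability_random=_reliability(P, C, R, E, c, k, random_rater=True),
        reliability_fixed=_reliability(P, C, R, E, c, k, random_rater=False),
    )


class ObserverCompetenceScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping item-level observer ratings to physician scores.

    ``transform`` takes a long observer-rating table (physician_id,
    consultation_id, rater_id, instrument, item_1..item_K) and returns a wide
    physician x instrument DataFrame of 0-100 competence scores.
    """

    def __init__(self, instruments: dict[str, InstrumentSpec] | None = None):
        self.instruments = instruments

    def fit(self, X: pd.DataFrame, y=None) -> "ObserverCompetenceScorer":
        self.instruments_ = dict(self.instruments or DEFAULT_INSTRUMENTS)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "instruments_"):
            self.fit(X)
        return competence_table(X, self.instruments_)
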