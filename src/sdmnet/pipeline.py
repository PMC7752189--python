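"""Stage-wise analysis pipeline and its file artifacts.

Stages (each writes CSV/JSON into ``config.outdir`` and logs record counts
and exclusions): simulate -> score-observer -> fit-network -> predict ->
report.  All randomness flows from the single configured seed through
deterministic per-stage child seeds, so a rerun with the same config yields
byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .network import N_SKILLS, SkillsNetwork, SkillsNetworkEstimator, node_parameters_wide
from .observer import competence_table, interrater_reliability, variance_decomposition
from .plotting import average_network, fruchterman_reingold_layout, render_reports
from .prediction import fit_final_model, fit_report, predict_competence, screen_predictors
from .simulate import simulate_study

logger = logging.getLogger("sdmnet.pipeline")

__all__ = ["PipelineError", "run_pipeline", "STAGES"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; partial outputs from earlier stages are retained."""


def _stage_seed(config: PipelineConfig, stage_index: int) -> int:
    return int(np.random.SeedSequence(config.seed).generate_state(8)[stage_index] % (2**31))


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)
    logger.info("wrote %s (%d records)", path, len(df))


def _setup_logging(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("sdmnet")
    root.setLevel(logging.INFO)
    have = {getattr(h, "_sdmnet_tag", None) for h in root.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        h._sdmnet_tag = "stderr"
        root.addHandler(h)
    logpath = outdir / "pipeline.log"
    for h in list(root.handlers):
        if getattr(h, "_sdmnet_tag", None) == "file" and getattr(h, "baseFilename", None) != str(
            logpath.resolve()
        ):
            root.removeHandler(h)
            h.close()
    if not any(
        getattr(h, "_sdmnet_tag", None) == "file"
        and getattr(h, "baseFilename", None) == str(logpath.resolve())
        for h in root.handlers
    ):
        h = logging.FileHandler(logpath)
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        h._sdmnet_tag = "file"
        root.addHandler(h)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig) -> None:
    if config.simulate is None:
        logger.info("no simulate block; skipping synthetic generation")
        return
    study = simulate_study(
        design=config.simulate, instruments=config.instruments, seed=config.seed
    )
    out = config.outdir
    _write_csv(study["patient_ratings"], out / "patient_ratings.csv")
    _write_csv(study["observer_ratings"], out / "observer_ratings.csv")
    _write_csv(study["true_node_parameters"], out / "true_node_parameters.csv")
    truth_rows = [
        {"physician_id": t.physician_id, **{f"true_{k}": v for k, v in t.competence_true.items()}}
        for t in study["truths"]
    ]
    _write_csv(pd.DataFrame(truth_rows), out / "true_competence.csv")


def _patient_path(config: PipelineConfig) -> Path:
    return config.patient_ratings_path or (config.outdir / "patient_ratings.csv")


def _observer_path(config: PipelineConfig) -> Path:
    return config.observer_ratings_path or (config.outdir / "observer_ratings.csv")


def _require(path: Path, stage: str) -> Path:
    if not Path(path).exists():
        raise FileNotFoundError(f"required input for {stage} not found: {path}")
    return Path(path)


def stage_score_observer(config: PipelineConfig) -> None:
    table = pd.read_csv(_require(_observer_path(config), "score-observer"))
    scores = competence_table(table, config.instruments)
    _write_csv(scores.reset_index(), config.outdir / "competence.csv")
    quality: dict = {}
    seed = _stage_seed(config, 1)
    for name, spec in config.instruments.items():
        if not (table["instrument"] == name).any():
            logger.warning("no observer records for %s; skipping quality checks", name)
            continue
        entry: dict = {}
        try:
            vd = variance_decomposition(table, spec)
            entry["variance_decomposition"] = {
                "var_physician": vd.var_physician,
                "var_consultation": vd.var_consultation,
                "var_residual": vd.var_residual,
                "icc": vd.icc,
                "zero_variance": vd.zero_variance,
                "n_physicians": vd.n_physicians,
            }
        except ValueError as exc:
            entry["variance_decomposition"] = {"error": str(exc)}
        try:
            irr = interrater_reliability(table, spec, mcmc=config.mcmc, seed=seed)
            entry["interrater_reliability"] = {
                "var_physician": irr.var_physician,
                "var_consultation": irr.var_consultation,
                "var_rater": irr.var_rater,
                "var_residual": irr.var_residual,
                "reliability_random": irr.reliability_random,
                "reliability_fixed": irr.reliability_fixed,
                "c": irr.c,
                "k": irr.k,
            }
        except ValueError as exc:
            entry["interrater_reliability"] = {"error": str(exc)}
        quality[name] = entry
    with open(config.outdir / "observer_quality.json", "w", encoding="utf-8") as fh:
        json.dump(quality, fh, indent=2, sort_keys=True)


def stage_fit_network(config: PipelineConfig) -> None:
    table = pd.read_csv(_require(_patient_path(config), "fit-network"))
    estimator = SkillsNetworkEstimator(
        model_selection=config.model_selection,
        purge_rule=config.purge_rule,
        purge_level=config.purge_level,
        activation=config.activation,
        mcmc=config.mcmc,
        seed=_stage_seed(config, 2),
        dic_threshold=config.dic_threshold,
    )
    estimator.fit(table)
    edges = pd.concat([net.edge_list() for net in estimator.networks_], ignore_index=True)
    _write_csv(edges, config.outdir / "edges.csv")
    _write_csv(estimator.node_parameters_, config.outdir / "node_parameters.csv")
    if estimator.comparisons_:
        comp = pd.DataFrame(
            [
                {
                    "outcome_skill": c.outcome_skill,
                    "dic_fixed": c.dic_fixed,
                    "dic_random": c.dic_random,
                    "dic_difference": c.dic_difference,
                    "selected": c.selected,
                }
                for c in estimator.comparisons_.values()
            ]
        )
        _write_csv(comp, config.outdir / "model_comparisons.csv")
    n_retained = int(sum(net.retained.sum() for net in estimator.networks_))
    logger.info(
        "fit-network: %d physicians, %d retained edges across networks",
        len(estimator.networks_),
        n_retained,
    )


def stage_predict(config: PipelineConfig) -> None:
    node_params = pd.read_csv(_require(config.outdir / "node_parameters.csv", "predict"))
    competence = pd.read_csv(_require(config.outdir / "competence.csv", "predict")).set_index(
        "physician_id"
    )
    wide = node_parameters_wide(node_params)
    seed = _stage_seed(config, 3)
    screening = screen_predictors(wide, competence, mcmc=config.mcmc, seed=seed)
    _write_csv(screening.table, config.outdir / "screening.csv")
    retained = screening.retained_skills
    if not retained:
        logger.warning("screening retained no skills; final models use all 9")
        retained = set(range(1, N_SKILLS + 1))
    logger.info("screening retained skills: %s", sorted(retained))

    coef_frames, predictions, stats = [], [], {}
    for i, outcome in enumerate(competence.columns):
        model = fit_final_model(
            wide, competence[outcome], retained, outcome=outcome,
            mcmc=config.mcmc, seed=seed + 1 + i,
        )
        preds = predict_competence(model, wide, observed=competence[outcome])
        report = fit_report(model, preds)
        coef_frames.append(report["coefficients"])
        predictions.append(preds)
        stats[outcome] = report["fit_statistics"]
    _write_csv(pd.concat(coef_frames, ignore_index=True), config.outdir / "model_coefficients.csv")
    _write_csv(pd.concat(predictions, ignore_index=True), config.outdir / "predictions.csv")
    with open(config.outdir / "fit_statistics.json", "w", encoding="utf-8") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)


def _networks_from_edges(edges: pd.DataFrame) -> list[SkillsNetwork]:
    networks = []
    for pid, grp in edges.groupby("physician_id", sort=True):
        W = np.zeros((N_SKILLS, N_SKILLS))
        lo = np.zeros((N_SKILLS, N_SKILLS))
        hi = np.zeros((N_SKILLS, N_SKILLS))
        ret = np.zeros((N_SKILLS, N_SKILLS), dtype=bool)
        for _, row in grp.iterrows():
            j, k = int(row["source_skill"]) - 1, int(row["target_skill"]) - 1
            W[j, k] = row["weight"]
            lo[j, k] = row["ci_low"]
            hi[j, k] = row["ci_high"]
            ret[j, k] = bool(row["retained"])
        networks.append(
            SkillsNetwork(physician_id=str(pid), weights=W, ci_low=lo, ci_high=hi, retained=ret)
        )
    return networks


def stage_report(config: PipelineConfig) -> None:
    node_params = pd.read_csv(_require(config.outdir / "node_parameters.csv", "report"))
    edges = pd.read_csv(_require(config.outdir / "edges.csv", "report"))
    networks = _networks_from_edges(edges)
    layout = fruchterman_reingold_layout(average_network(networks), seed=_stage_seed(config, 4))
    layout_df = pd.DataFrame(
        [
            {"skill": node, "x": xy[0], "y": xy[1]}
            for node, xy in sorted(layout.coordinates.items())
        ]
    )
    _write_csv(layout_df, config.outdir / "network_layout.csv")
    predictions = None
    pred_path = config.outdir / "predictions.csv"
    if pred_path.exists():
        predictions = pd.read_csv(pred_path)
    if config.figures:
        render_reports(
            node_params, networks, predictions, config.outdir, seed=_stage_seed(config, 4)
        )
    else:
        logger.info("figures disabled; wrote layout coordinates only")


STAGES: dict[str, callable] = {
    "simulate": stage_simulate,
    "score-observer": stage_score_observer,
    "fit-network": stage_fit_network,
    "predict": stage_predict,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> None:
    """Execute the requested stages in canonical order.

    Any stage failure raises :class:`PipelineError` tagged with the stage
    name; outputs already written by earlier stages are retained.
    """
    _setup_logging(config.outdir)
    config.validate_inputs()
    for name in stages or list(STAGES):
        if name not in STAGES:
            raise ValueError(f"unknown stage: {name}")
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            STAGES[name](config)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
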