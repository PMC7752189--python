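"""Network layout and report figures.

Layout uses the Fruchterman-Reingold force-directed algorithm with edge
attraction on the absolute purged weight, so strongly associated skills end
up close together; the sign of an edge is shown by arrow style, not
distance.  Figures mirror the analysis outputs: node-parameter bar panels,
the average network with arrow width proportional to |weight|, per-physician
small multiples, and the observed-vs-predicted competence scatter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import N_SKILLS, SkillsNetwork

logger = logging.getLogger(__name__)

__all__ = ["LayoutResult", "fruchterman_reingold_layout", "average_network", "render_reports"]


@dataclass(frozen=True)
class LayoutResult:
    """Deterministic 2-D node placement."""

    coordinates: dict[int, tuple[float, float]]  # skill -> (x, y)
    iterations: int
    seed: int


def _weight_graph(weights: np.ndarray) -> nx.DiGraph:
    g = nx.DiGraph()
    n = weights.shape[0]
    g.add_nodes_from(range(1, n + 1))
    for j in range(n):
        for k in range(n):
            if j != k and weights[j, k] != 0:
                g.add_edge(j + 1, k + 1, weight=abs(float(weights[j, k])))
    return g


def fruchterman_reingold_layout(
    network: SkillsNetwork | np.ndarray, iterations: int = 50, seed: int = 0
) -> LayoutResult:
    """Force-directed layout on |purged weight| (Fruchterman-Reingold).

    Stronger edges act as stronger springs, pulling the corresponding skills
    together; the result is deterministic given the seed.
    """
    weights = network.purged_weights if isinstance(network, SkillsNetwork) else np.asarray(network)
    g = _weight_graph(weights)
    if g.number_of_nodes() == 1:
        coords = {next(iter(g.nodes)): (0.0, 0.0)}
    else:
        pos = nx.spring_layout(g, iterations=iterations, seed=seed, weight="weight")
        coords = {node: (float(xy[0]), float(xy[1])) for node, xy in pos.items()}
    if not all(np.isfinite(list(xy)).all() for xy in coords.values()):
        raise FloatingPointError("layout produced non-finite coordinates")
    return LayoutResult(coordinates=coords, iterations=iterations, seed=seed)


def average_network(networks: list[SkillsNetwork]) -> np.ndarray:
    """Element-wise mean of the purged weight matrices across physicians."""
    if not networks:
        raise ValueError("no networks to average")
    return np.mean([net.purged_weights for net in networks], axis=0)


def _draw_network(ax, weights: np.ndarray, layout: LayoutResult, title: str) -> None:
    g = _weight_graph(weights)
    pos = {n: layout.coordinates[n] for n in g.nodes}
    max_w = max((abs(weights).max(), 1e-9))
    widths = [4.0 * g.edges[e]["weight"] / max_w for e in g.edges]
    styles = ["solid" if weights[e[0] - 1, e[1] - 1] > 0 else "dashed" for e in g.edges]
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#c6dbef", node_size=350)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    if g.number_of_edges():
        nx.draw_networkx_edges(
            g, pos, ax=ax, width=widths, style=styles, arrows=True, arrowsize=8,
            connectionstyle="arc3,rad=0.1",
        )
    ax.set_title(title, fontsize=9)
    ax.set_axis_off()


def render_reports(
    node_params: pd.DataFrame | None,
    networks: list[SkillsNetwork] | None,
    predictions: pd.DataFrame | None,
    outdir: str | Path,
    seed: int = 0,
    max_small_multiples: int = 30,
) -> list[Path]:
    """Write the report figures; stages with missing inputs are skipped with
    a warning.  Returns the paths written."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if node_params is not None and not node_params.empty:
        means = node_params.groupby("skill")[["activation", "outstrength", "instrength"]].mean()
        fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
        for ax, col in zip(axes, ["activation", "outstrength", "instrength"]):
            ax.bar(means.index, means[col], color="#4292c6")
            ax.set_title(f"average {col}", fontsize=9)
            ax.set_xlabel("skill")
        fig.tight_layout()
        path = outdir / "node_parameters.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    else:
        logger.warning("render_reports: no node parameters; skipping bar panels")

    if networks:
        avg = average_network(networks)
        layout = fruchterman_reingold_layout(avg, seed=seed)
        fig, ax = plt.subplots(figsize=(5, 5))
        _draw_network(ax, avg, layout, "average skills network")
        path = outdir / "average_network.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

        subset = networks[:max_small_multiples]
        ncol = 5
        nrow = int(np.ceil(len(subset) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(2.4 * ncol, 2.4 * nrow))
        for ax, net in zip(np.atleast_1d(axes).ravel(), subset):
            _draw_network(ax, net.purged_weights, layout, net.physician_id)
        for ax in np.atleast_1d(axes).ravel()[len(subset):]:
            ax.set_axis_off()
        fig.tight_layout()
        path = outdir / "physician_networks.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    else:
        logger.warning("render_reports: no networks; skipping network plots")

    if predictions is not None and "observed_score" in getattr(predictions, "columns", []):
        fig, axes_list = plt.subplots(
            1, predictions["outcome"].nunique(), figsize=(3.4 * predictions["outcome"].nunique(), 3.4),
            squeeze=False,
        )
        for ax, (outcome, grp) in zip(axes_list[0], predictions.groupby("outcome")):
            obs = grp.dropna(subset=["observed_score"])
            ax.scatter(grp["predicted_score"], grp["observed_score"], s=18, color="#2171b5")
            if len(obs) >= 3:
                from statsmodels.nonparametric.smoothers_lowess import lowess

                sm = lowess(obs["observed_score"], obs["predicted_score"], frac=0.8)
                ax.plot(sm[:, 0], sm[:, 1], color="grey")
            ax.set_xlabel("predicted")
            ax.set_ylabel("observed")
            ax.set_title(outcome, fontsize=9)
        fig.tight_layout()
        path = outdir / "predicted_vs_observed.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    else:
        logger.warning("render_reports: no predictions with observations; skipping scatter")
    return written
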