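"""Matplotlib figures: dendrogram, networks, trajectories, strength forest.

Layouts are cosmetic; spring layouts are seeded for reproducibility but
carry no statistical meaning.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .cluster import ClusterSolution
from .networks import UndirectedNetwork

__all__ = [
    "plot_dendrogram",
    "plot_undirected_network",
    "plot_directed_network",
    "plot_trajectories",
    "plot_strength_forest",
]


def _ax(ax, figsize):
    if ax is None:
        _, ax = plt.subplots(figsize=figsize)
    return ax


def plot_dendrogram(solution: ClusterSolution, ax=None):
    ax = _ax(ax, (8, 4))
    hierarchy.dendrogram(
        solution.linkage_matrix,
        labels=list(solution.attributes),
        ax=ax,
        leaf_rotation=90,
        color_threshold=0.0,
        above_threshold_color="k",
    )
    ax.set_ylabel("merge height (DTW distance)")
    ax.set_title(f"Attribute dendrogram (k = {solution.k})")
    ax.figure.tight_layout()
    return ax


def plot_undirected_network(network: UndirectedNetwork, ax=None, seed: int = 0):
    ax = _ax(ax, (7, 7))
    g = network.to_graph()
    pos = nx.spring_layout(g, weight="weight", seed=seed)
    node_colors = [g.nodes[n].get("color", "#cccccc") for n in g]
    weights = np.array([d["weight"] for _, _, d in g.edges(data=True)])
    edge_colors = [
        "green" if d["sign"] == "positive" else "red" for _, _, d in g.edges(data=True)
    ]
    nx.draw_networkx_edges(
        g, pos, ax=ax, width=3.0 * weights, edge_color=edge_colors, alpha=0.5
    )
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color=node_colors, node_size=900)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=7)
    ax.set_title("Undirected co-occurrence network (node color = dimension)")
    ax.set_axis_off()
    return ax


def plot_directed_network(graph: nx.DiGraph, ax=None, seed: int = 0):
    ax = _ax(ax, (7, 7))
    pos = nx.spring_layout(graph, seed=seed)
    edge_colors = [
        "green" if d.get("sign") == "positive" else "red"
        for _, _, d in graph.edges(data=True)
    ]
    widths = [1.0 + 8.0 * abs(d.get("weight", 0.1)) for _, _, d in graph.edges(data=True)]
    nx.draw_networkx_nodes(graph, pos, ax=ax, node_color="#dddddd", node_size=900)
    nx.draw_networkx_labels(graph, pos, ax=ax, font_size=7)
    nx.draw_networkx_edges(
        graph, pos, ax=ax, width=widths, edge_color=edge_colors,
        arrows=True, arrowsize=15, connectionstyle="arc3,rad=0.1",
    )
    n_edges = graph.number_of_edges()
    title = "Directed temporal-precedence network"
    if n_edges == 0:
        title += " (no significant directed edges)"
    ax.set_title(title)
    ax.set_axis_off()
    return ax


def plot_trajectories(summary: pd.DataFrame, ax=None):
    ax = _ax(ax, (8, 5))
    for attr, grp in summary.groupby("attribute"):
        grp = grp.sort_values("time")
        ax.errorbar(
            grp["time"], grp["mean"], yerr=grp["se"], label=attr,
            marker="o", markersize=3, capsize=2, linewidth=1,
        )
    ax.set_xlabel("assessment")
    ax.set_ylabel("group mean (observed values)")
    ax.set_title("Mean attribute trajectories")
    ax.legend(fontsize=6, ncol=2)
    ax.figure.tight_layout()
    return ax


def plot_strength_forest(strengths: pd.DataFrame, ax=None):
    ax = _ax(ax, (7, 8))
    order = (
        strengths[strengths["kind"] == "out"]
        .sort_values("estimate")["node"].tolist()
    )
    y = np.arange(len(order))
    for kind, offset, color in (("out", 0.15, "tab:blue"), ("in", -0.15, "tab:orange")):
        sub = strengths[strengths["kind"] == kind].set_index("node").loc[order]
        ax.errorbar(
            sub["estimate"], y + offset,
            xerr=[sub["estimate"] - sub["ci_low"], sub["ci_high"] - sub["estimate"]],
            fmt="o", color=color, label=f"{kind}-strength", capsize=2, markersize=4,
        )
    ax.axvline(0.0, color="k", linewidth=0.8)
    ax.set_yticks(y, order, fontsize=7)
    ax.set_xlabel("standardized strength (95% CI)")
    ax.set_title("Out-/in-strength centralities")
    ax.legend(fontsize=8)
    ax.figure.tight_layout()
    return ax
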