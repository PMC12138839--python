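"""Network artifacts: signed undirected co-occurrence and directed graphs.

Undirected edge weights use the similarity transform ``s = 1 / (1 + d)``
of the group DTW distance (monotone decreasing, bounded in (0, 1]; any
strictly decreasing transform preserves the layout topology).  Edge sign
follows the two attributes' *original* valences: same valence -> positive
("green"), opposite -> negative ("red").  Nodes carry cluster ids and a
deterministic per-cluster color.  Graphs are exported as GraphML (via
networkx) and as a JSON edge list that round-trips.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .cluster import ClusterSolution
from .directed import DirectedEdge, StrengthEstimate
from .schema import AttributeSchema

__all__ = [
    "UndirectedNetwork",
    "undirected_network",
    "directed_graph",
    "write_graphml",
    "write_edges_json",
    "read_edges_json",
    "cluster_colors",
]

# tab10-style palette; cluster ids are small so cycling is acceptable
_PALETTE = (
    "#d62728", "#9467bd", "#1f77b4", "#2ca02c", "#ff7f0e",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


def cluster_colors(cluster_ids: Sequence[int]) -> dict[int, str]:
    return {c: _PALETTE[(c - 1) % len(_PALETTE)] for c in sorted(set(cluster_ids))}


@dataclass(frozen=True)
class UndirectedNetwork:
    """Clustered, signed co-occurrence network over attributes."""

    nodes: tuple[dict, ...]  # name, label, cluster, color
    edges: tuple[dict, ...]  # source, target, distance, weight, sign

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n["name"], **{k: v for k, v in n.items() if k != "name"})
        for e in self.edges:
            g.add_edge(e["source"], e["target"], **{k: v for k, v in e.items() if k not in ("source", "target")})
        return g


def undirected_network(
    group_matrix: np.ndarray,
    solution: ClusterSolution,
    schema: AttributeSchema,
) -> UndirectedNetwork:
    """Build the signed undirected network from the group distance matrix
    and a cluster solution (full graph; one edge per attribute pair)."""
    attrs = solution.attributes
    d = np.asarray(group_matrix, dtype=float)
    if d.shape != (len(attrs), len(attrs)):
        raise ValueError("matrix shape does not match cluster solution")
    colors = cluster_colors(solution.labels.values())
    nodes = tuple(
        {
            "name": a,
            "label": schema[a].label if a in schema else a,
            "cluster": solution.labels[a],
            "color": colors[solution.labels[a]],
        }
        for a in attrs
    )
    edges = []
    for i, a in enumerate(attrs):
        for j in range(i + 1, len(attrs)):
            b = attrs[j]
            va = schema[a].higher_is_worse if a in schema else True
            vb = schema[b].higher_is_worse if b in schema else True
            edges.append(
                {
                    "source": a,
                    "target": b,
                    "distance": float(d[i, j]),
                    "weight": 1.0 / (1.0 + float(d[i, j])),
                    "sign": "positive" if va == vb else "negative",
                }
            )
    return UndirectedNetwork(nodes, tuple(edges))


def directed_graph(
    edges: Sequence[DirectedEdge],
    strengths: Sequence[StrengthEstimate],
    schema: Optional[AttributeSchema] = None,
    significant_only: bool = True,
) -> nx.DiGraph:
    """Directed temporal-precedence graph with strength annotations.

    Arrows are the (by default significant) a -> b edges, weighted by the
    group-mean direction contrast; edge sign again reflects original
    valences.
    """
    g = nx.DiGraph()
    by_node: dict[str, dict] = {}
    for s in strengths:
        by_node.setdefault(s.node, {})
        by_node[s.node][f"{s.kind}_strength"] = s.standardized_mean
        by_node[s.node][f"{s.kind}_significant"] = s.significant
    for node, attrs in by_node.items():
        label = schema[node].label if schema is not None and node in schema else node
        g.add_node(node, label=label, **attrs)
    for e in edges:
        if significant_only and not e.significant:
            continue
        same_valence = True
        if schema is not None and e.source in schema and e.target in schema:
            same_valence = (
                schema[e.source].higher_is_worse == schema[e.target].higher_is_worse
            )
        g.add_edge(
            e.source,
            e.target,
            weight=e.mean_delta,
            p_value=e.p_value,
            sign="positive" if same_valence else "negative",
        )
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, path)


def write_edges_json(network: UndirectedNetwork | nx.DiGraph, path) -> None:
    """JSON edge-list export; round-trips through :func:`read_edges_json`."""
    if isinstance(network, UndirectedNetwork):
        payload = {"directed": False, "nodes": list(network.nodes), "edges": list(network.edges)}
    else:
        payload = {
            "directed": True,
            "nodes": [{"name": n, **d} for n, d in network.nodes(data=True)],
            "edges": [{"source": u, "target": v, **d} for u, v, d in network.edges(data=True)],
        }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_edges_json(path) -> dict:
    return json.loads(Path(path).read_text())
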