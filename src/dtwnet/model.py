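"""Model/results interface tying the pipeline together.

:class:`DtwNetworkModel` is constructed from a complete panel dataset (or
an imputation stack of complete replicates) plus an attribute schema and
the analysis settings; ``fit()`` runs preprocessing, the undirected and
directed DTW stages, clustering and the group-level inference, and returns
a :class:`DtwNetworkResults` carrying every estimate with its uncertainty,
a ``summary()`` table, artifact writers and plotting helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cluster import ClusterSolution, cluster_attributes, linkage_to_newick
from .directed import (
    DirectedDeltaTensor,
    DirectedEdge,
    StrengthEstimate,
    directed_deltas,
    edges_frame,
    pool_deltas,
    strength_centrality,
    strengths_frame,
    test_directed_edges,
)
from .distances import (
    DistanceTensor,
    aggregate_group,
    subject_distance_matrices,
    trajectory_summary,
    write_matrix_csv,
)
from .networks import (
    UndirectedNetwork,
    directed_graph,
    undirected_network,
    write_edges_json,
    write_graphml,
)
from .panel import PanelDataset, read_imputation_stack, read_long_csv
from .preprocess import preprocess
from .schema import AttributeSchema

__all__ = ["DtwNetworkModel", "DtwNetworkResults"]


class DtwNetworkModel:
    """DTW symptom-network model for short panel time series.

    Parameters
    ----------
    data : PanelDataset or sequence of PanelDataset
        A complete dataset, or a stack of complete imputed replicates
        (analyses run per replicate and averaged).
    schema : AttributeSchema, optional
        Attribute valences and labels; defaults to all-higher-is-worse.
    window : int
        Sakoe-Chiba half-width for the undirected alignment (default 1).
    max_lag : int
        Forward lag bound of the directed alignment (default 1).
    linkage : str
        Agglomerative linkage for the dimension clustering
        (``ward``/``average``/``complete``).
    k_range : (int, int), optional
        Candidate cluster counts; default ``(2, K - 1)``.
    alpha : float
        One-sided level for directed-edge tests (default 0.05).
    test_method : str
        ``t`` (default) or ``wilcoxon`` for the group-level edge test.
    correction : str, optional
        ``bonferroni`` or ``bh``; default none (the node-level strength
        tests are the main outcome family).
    directed : bool
        Set False to skip the directed stage entirely.
    """

    def __init__(
        self,
        data: PanelDataset | Sequence[PanelDataset],
        schema: Optional[AttributeSchema] = None,
        *,
        window: int = 1,
        max_lag: int = 1,
        linkage: str = "ward",
        k_range: Optional[tuple[int, int]] = None,
        alpha: float = 0.05,
        test_method: str = "t",
        correction: Optional[str] = None,
        directed: bool = True,
    ):
        if isinstance(data, PanelDataset):
            stack = [data]
        else:
            stack = list(data)
            if not stack:
                raise ValueError("empty imputation stack")
        for ds in stack:
            if not ds.is_complete():
                raise ValueError(
                    "dataset contains missing values; provide an imputation "
                    "stack of complete replicates"
                )
        first = stack[0]
        for ds in stack[1:]:
            if (ds.subjects, ds.timepoints, ds.attributes) != (
                first.subjects, first.timepoints, first.attributes,
            ):
                raise ValueError("imputation replicates differ in shape")
        if schema is None:
            schema = AttributeSchema.from_names(first.attributes)
        missing = set(first.attributes) - set(schema.names)
        if missing:
            raise ValueError(f"attribute(s) not in schema: {sorted(missing)}")
        self.stack = stack
        self.schema = schema
        self.window = int(window)
        self.max_lag = int(max_lag)
        self.linkage = linkage
        self.k_range = k_range
        self.alpha = float(alpha)
        self.test_method = test_method
        self.correction = correction
        self.directed = bool(directed)

    # -- constructors --------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema=None, **kwargs) -> "DtwNetworkModel":
        """Build from a long-format frame (subject/time/attribute/value,
        optionally an ``imputation`` column for stacks)."""
        if "imputation" in df.columns:
            indices = sorted(pd.to_numeric(df["imputation"]).astype(int).unique())
            if indices != list(range(1, len(indices) + 1)):
                raise ValueError(f"non-contiguous imputation indices: {indices}")
            stack = [
                PanelDataset.from_long_frame(
                    df[df["imputation"].astype(int) == m].drop(columns=["imputation"]),
                    schema,
                    imputation_index=m,
                )
                for m in indices
            ]
            return cls(stack, schema, **kwargs)
        return cls(PanelDataset.from_long_frame(df, schema), schema, **kwargs)

    @classmethod
    def from_long_csv(cls, path, schema=None, **kwargs) -> "DtwNetworkModel":
        return cls(read_long_csv(path, schema), schema, **kwargs)

    @classmethod
    def from_imputation_stack(cls, path, schema=None, **kwargs) -> "DtwNetworkModel":
        return cls(read_imputation_stack(path, schema), schema, **kwargs)

    # -- estimation ----------------------------------------------------
    def fit(self) -> "DtwNetworkResults":
        """Run the full pipeline and return the results object."""
        processed = [preprocess(ds, self.schema) for ds in self.stack]

        distance = aggregate_group(
            [subject_distance_matrices(ds, self.window) for ds in processed]
        )
        solution = cluster_attributes(
            distance.group_matrix,
            distance.attributes,
            k_range=self.k_range,
            linkage=self.linkage,
        )
        undirected = undirected_network(distance.group_matrix, solution, self.schema)

        delta = edges = strengths = None
        if self.directed:
            delta = pool_deltas(
                [directed_deltas(ds, self.max_lag) for ds in processed]
            )
            edges = test_directed_edges(
                delta, alpha=self.alpha, method=self.test_method,
                correction=self.correction,
            )
            strengths = strength_centrality(delta)

        raw = self.stack[0]
        if len(self.stack) > 1:
            raw = raw.with_values(np.mean([d.values for d in self.stack], axis=0))
        trajectories = trajectory_summary(raw)

        return DtwNetworkResults(
            model=self,
            distance_tensor=distance,
            cluster_solution=solution,
            undirected=undirected,
            delta_tensor=delta,
            directed_edges=tuple(edges) if edges is not None else None,
            strengths=tuple(strengths) if strengths is not None else None,
            trajectories=trajectories,
        )

    def settings(self) -> dict:
        """Everything needed to reproduce a fit bit-for-bit (given the data)."""
        return {
            "package_version": _pkg_version,
            "window": self.window,
            "max_lag": self.max_lag,
            "linkage": self.linkage,
            "k_rule": "max mean silhouette, ties to smaller k",
            "k_range": list(self.k_range) if self.k_range else None,
            "alpha": self.alpha,
            "test_method": self.test_method,
            "correction": self.correction,
            "directed": self.directed,
            "n_imputations": len(self.stack),
            "edge_weight_transform": "1/(1+d)",
        }


@dataclass(frozen=True)
class DtwNetworkResults:
    """Fitted DTW symptom network: clustered undirected structure, directed
    temporal-precedence edges and strength centralities with 95% CIs."""

    model: DtwNetworkModel
    distance_tensor: DistanceTensor
    cluster_solution: ClusterSolution
    undirected: UndirectedNetwork
    delta_tensor: Optional[DirectedDeltaTensor]
    directed_edges: Optional[tuple[DirectedEdge, ...]]
    strengths: Optional[tuple[StrengthEstimate, ...]]
    trajectories: pd.DataFrame = field(repr=False)

    # -- accessors -----------------------------------------------------
    @property
    def attributes(self) -> tuple[str, ...]:
        return self.distance_tensor.attributes

    @property
    def k(self) -> int:
        return self.cluster_solution.k

    @property
    def n_main_outcome_tests(self) -> int:
        """Number of node-level main-outcome (out-strength) tests: one per
        attribute."""
        return len(self.attributes)

    def significant_edges(self) -> tuple[DirectedEdge, ...]:
        if self.directed_edges is None:
            return ()
        return tuple(e for e in self.directed_edges if e.significant)

    def significant_strengths(self, kind: Optional[str] = None) -> tuple[StrengthEstimate, ...]:
        if self.strengths is None:
            return ()
        return tuple(
            s for s in self.strengths
            if s.significant and (kind is None or s.kind == kind)
        )

    def strength(self, node: str, kind: str) -> StrengthEstimate:
        for s in self.strengths or ():
            if s.node == node and s.kind == kind:
                return s
        raise KeyError((node, kind))

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary (dimensions, edges, strengths)."""
        lines = []
        n, t, k = self.model.stack[0].shape
        lines.append("DTW Symptom Network Results")
        lines.append("=" * 64)
        lines.append(
            f"subjects: {n}   timepoints: {t}   attributes: {k}   "
            f"imputations pooled: {len(self.model.stack)}"
        )
        s = self.model.settings()
        lines.append(
            f"window: {s['window']}   max_lag: {s['max_lag']}   "
            f"linkage: {s['linkage']}   alpha: {s['alpha']}"
        )
        lines.append("")
        lines.append(f"Dimensions (k = {self.k}, chosen by mean silhouette width):")
        for cid in sorted(set(self.cluster_solution.labels.values())):
            members = ", ".join(self.cluster_solution.members(cid))
            lines.append(f"  [{cid}] {members}")
        sil = self.cluster_solution.silhouette_by_k
        lines.append(
            "  silhouette by k: "
            + "  ".join(f"{kk}: {v:.3f}" for kk, v in sorted(sil.items()))
        )
        if self.directed_edges is not None:
            sig = self.significant_edges()
            lines.append("")
            lines.append(
                f"Directed edges (one-sided {self.model.test_method}-test, "
                f"alpha = {self.model.alpha}): {len(sig)} significant"
            )
            for e in sorted(sig, key=lambda e: e.p_value)[:20]:
                lines.append(
                    f"  {e.source} -> {e.target}: mean delta = {e.mean_delta:+.4f} "
                    f"(se {e.se:.4f}, p = {e.p_value:.4g})"
                )
            lines.append("")
            lines.append("Standardized strengths (mean [95% CI], * CI > 0):")
            for kind, title in (("out", "out-strength (temporal lead)"),
                                ("in", "in-strength (temporal lag)")):
                lines.append(f"  {title}:")
                for st in sorted(
                    (x for x in self.strengths if x.kind == kind),
                    key=lambda x: -x.standardized_mean,
                ):
                    flag = " *" if st.significant else ""
                    lines.append(
                        f"    {st.node:<20s} {st.standardized_mean:+.4f} "
                        f"[{st.ci_low:+.4f}, {st.ci_high:+.4f}]{flag}"
                    )
        return "\n".join(lines)

    def run_summary(self) -> dict:
        """JSON-ready machine summary; deterministic for a given data+seed
        (no timestamps)."""
        out = {
            "settings": self.model.settings(),
            "n_subjects": len(self.model.stack[0].subjects),
            "n_timepoints": len(self.model.stack[0].timepoints),
            "attributes": list(self.attributes),
            "k": self.k,
            "cluster_labels": dict(self.cluster_solution.labels),
            "silhouette_by_k": {str(kk): v for kk, v in self.cluster_solution.silhouette_by_k.items()},
            "n_main_outcome_tests": self.n_main_outcome_tests,
        }
        if self.directed_edges is not None:
            out["significant_edges"] = [
                {"source": e.source, "target": e.target,
                 "mean_delta": e.mean_delta, "p": e.p_value}
                for e in self.significant_edges()
            ]
            out["significant_out_strength"] = [s.node for s in self.significant_strengths("out")]
            out["significant_in_strength"] = [s.node for s in self.significant_strengths("in")]
        return out

    # -- artifacts -----------------------------------------------------
    def save_artifacts(self, outdir) -> Path:
        """Write every file artifact of the fit into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix_csv(
            self.distance_tensor.group_matrix, self.attributes,
            outdir / "group_distance_matrix.csv",
        )
        np.savetxt(
            outdir / "linkage_matrix.csv", self.cluster_solution.linkage_matrix,
            delimiter=",", header="merge_a,merge_b,height,count", comments="",
        )
        (outdir / "dendrogram.nwk").write_text(linkage_to_newick(self.cluster_solution) + "\n")
        write_graphml(self.undirected.to_graph(), outdir / "undirected_network.graphml")
        write_edges_json(self.undirected, outdir / "undirected_network.json")
        self.trajectories.to_csv(outdir / "trajectory_summary.csv", index=False)
        if self.directed_edges is not None:
            edges_frame(self.directed_edges).to_csv(outdir / "directed_edges.csv", index=False)
            strengths_frame(self.strengths).to_csv(outdir / "strengths.csv", index=False)
            g = directed_graph(self.directed_edges, self.strengths, self.model.schema)
            write_graphml(g, outdir / "directed_network.graphml")
            write_edges_json(g, outdir / "directed_network.json")
        (outdir / "run_summary.json").write_text(
            json.dumps(self.run_summary(), indent=2, sort_keys=True) + "\n"
        )
        return outdir

    # -- plots ---------------------------------------------------------
    def plot_dendrogram(self, ax=None):
        from .plotting import plot_dendrogram

        return plot_dendrogram(self.cluster_solution, ax=ax)

    def plot_network(self, ax=None, seed: int = 0):
        from .plotting import plot_undirected_network

        return plot_undirected_network(self.undirected, ax=ax, seed=seed)

    def plot_directed_network(self, ax=None, seed: int = 0):
        from .plotting import plot_directed_network

        g = directed_graph(self.directed_edges, self.strengths, self.model.schema)
        return plot_directed_network(g, ax=ax, seed=seed)

    def plot_trajectories(self, ax=None):
        from .plotting import plot_trajectories

        return plot_trajectories(self.trajectories, ax=ax)

    def plot_strengths(self, ax=None):
        from .plotting import plot_strength_forest

        return plot_strength_forest(strengths_frame(self.strengths), ax=ax)
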