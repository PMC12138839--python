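"""Hierarchical clustering of attributes into dimensions.

Agglomerative clustering is run on the group-level DTW distance matrix
(treated as the dissimilarity).  The number of clusters ("dimensions") is
chosen data-dependently by maximising the mean silhouette width over a
candidate range, ties resolved toward the smaller, more parsimonious k.
Ward linkage is the default (average and complete are also supported);
linkage, the k-selection rule and the candidate range are configurable and
recorded in output metadata, since none of them is forced by the method
itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = ["ClusterSolution", "cluster_attributes", "linkage_to_newick"]

_LINKAGES = ("ward", "average", "complete")


@dataclass(frozen=True)
class ClusterSolution:
    """A cut agglomerative tree over attributes.

    ``labels`` maps each attribute to a 1-based cluster id consistent with
    cutting ``linkage_matrix`` (scipy format) into ``k`` groups;
    ``silhouette_by_k`` records the selection trace.
    """

    attributes: tuple[str, ...]
    linkage_matrix: np.ndarray = field(repr=False)
    k: int
    labels: dict[str, int]
    silhouette_by_k: dict[int, float]
    linkage_method: str = "ward"

    def labels_array(self) -> np.ndarray:
        return np.array([self.labels[a] for a in self.attributes])

    def members(self, cluster_id: int) -> tuple[str, ...]:
        return tuple(a for a in self.attributes if self.labels[a] == cluster_id)


def cluster_attributes(
    group_matrix: np.ndarray,
    attributes,
    k_range: tuple[int, int] | None = None,
    linkage: str = "ward",
) -> ClusterSolution:
    """Cluster attributes on a distance matrix, choosing k by mean silhouette.

    Parameters
    ----------
    group_matrix : (K, K) array
        Symmetric nonnegative distance matrix with zero diagonal, K >= 3.
    attributes : sequence of str
        Names, in matrix order.
    k_range : (lo, hi), optional
        Inclusive candidate range; defaults to ``(2, K - 1)``.
    linkage : str
        One of ``ward`` (default), ``average``, ``complete``.
    """
    d = np.asarray(group_matrix, dtype=float)
    attributes = tuple(attributes)
    k_attrs = len(attributes)
    if d.shape != (k_attrs, k_attrs):
        raise ValueError("matrix shape does not match attribute count")
    if k_attrs < 3:
        raise ValueError("need at least 3 attributes to cluster")
    if not np.allclose(d, d.T) or np.any(d < 0):
        raise ValueError("invalid distance matrix")
    if np.all(d == 0):
        raise ValueError("degenerate distance matrix (all zeros)")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")

    lo, hi = k_range if k_range is not None else (2, k_attrs - 1)
    if not (2 <= lo <= hi <= k_attrs):
        raise ValueError(f"invalid k_range ({lo}, {hi}) for K={k_attrs}")

    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)

    def cut(k: int) -> np.ndarray:
        # cut_tree yields exactly k groups even under tied merge heights
        return hierarchy.cut_tree(z, n_clusters=k).ravel() + 1

    sil: dict[int, float] = {}
    best_k, best_s = None, -np.inf
    for k in range(lo, hi + 1):
        lab = cut(k)
        if k == k_attrs:
            s = 0.0  # silhouette undefined for singleton-only partitions
        else:
            s = float(silhouette_score(d, lab, metric="precomputed"))
        sil[k] = s
        if s > best_s + 1e-12:  # ties resolve to the smaller k
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no valid partition in the requested k range")
    lab = cut(best_k)
    return ClusterSolution(
        attributes=attributes,
        linkage_matrix=z,
        k=int(best_k),
        labels={a: int(c) for a, c in zip(attributes, lab)},
        silhouette_by_k=sil,
        linkage_method=linkage,
    )


def linkage_to_newick(solution: ClusterSolution) -> str:
    """Render the merge tree as Newick text with merge heights as branch lengths."""
    tree = hierarchy.to_tree(solution.linkage_matrix)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{solution.attributes[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
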