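"""Per-subject DTW distance matrices and their group-level aggregation.

For every subject the ``K x K`` symmetric matrix of pairwise undirected
DTW distances between that subject's (preprocessed) attribute trajectories
is computed.  Group aggregation averages elementwise -- first across
imputation replicates (each replicate analysed separately and the analyses
averaged), then across subjects.  For elementwise means the two stages
commute; the order is pinned for reproducibility of intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dtw import dtw_undirected_batch
from .panel import PanelDataset

__all__ = [
    "DistanceTensor",
    "subject_distance_matrices",
    "aggregate_group",
    "trajectory_summary",
    "write_matrix_csv",
    "read_matrix_csv",
]


@dataclass(frozen=True)
class DistanceTensor:
    """Subject-wise ``(S, K, K)`` distance matrices plus the group aggregate."""

    subjects: tuple[str, ...]
    attributes: tuple[str, ...]
    per_subject: np.ndarray = field(repr=False)  # (S, K, K)
    group_matrix: np.ndarray | None = field(default=None, repr=False)  # (K, K)
    n_imputations_pooled: int = 1

    def __post_init__(self):
        ps = np.asarray(self.per_subject, dtype=float)
        s, k = len(self.subjects), len(self.attributes)
        if ps.shape != (s, k, k):
            raise ValueError(f"per_subject shape {ps.shape} != ({s}, {k}, {k})")
        if np.any(ps < 0) or not np.allclose(ps, ps.transpose(0, 2, 1)):
            raise ValueError("per-subject matrices must be nonnegative and symmetric")
        if not np.allclose(np.diagonal(ps, axis1=1, axis2=2), 0.0):
            raise ValueError("per-subject matrices must have zero diagonal")
        object.__setattr__(self, "per_subject", ps)
        if self.group_matrix is not None:
            gm = np.asarray(self.group_matrix, dtype=float)
            if gm.shape != (k, k):
                raise ValueError("group_matrix shape mismatch")
            object.__setattr__(self, "group_matrix", gm)

    def recompute_group(self) -> np.ndarray:
        """Elementwise mean of the per-subject matrices (the stored aggregate
        must equal this)."""
        return self.per_subject.mean(axis=0)

    def group_frame(self) -> pd.DataFrame:
        if self.group_matrix is None:
            raise ValueError("group_matrix not filled; call aggregate_group first")
        return pd.DataFrame(self.group_matrix, index=self.attributes, columns=self.attributes)


def subject_distance_matrices(ds: PanelDataset, window: int = 1) -> DistanceTensor:
    """Pairwise undirected DTW distances per subject.

    Requires a complete (imputed) and preprocessed dataset.  Entry
    ``(a, b)`` of subject ``s`` is the banded symmetric2 DTW distance
    between the subject's two attribute trajectories.
    """
    if not ds.is_complete():
        raise ValueError("dataset contains missing values; impute before DTW")
    s, _, k = ds.shape
    out = np.zeros((s, k, k))
    for a in range(k):
        for b in range(a + 1, k):
            d = dtw_undirected_batch(ds.values[:, :, a], ds.values[:, :, b], window)
            out[:, a, b] = d
            out[:, b, a] = d
    return DistanceTensor(ds.subjects, ds.attributes, out)


def aggregate_group(tensors: Sequence[DistanceTensor]) -> DistanceTensor:
    """Pool distance tensors over imputation replicates and aggregate.

    Per-subject matrices are averaged elementwise across replicates first;
    the group matrix is then the elementwise mean across subjects.
    """
    if not tensors:
        raise ValueError("no tensors to aggregate")
    first = tensors[0]
    for t in tensors[1:]:
        if t.subjects != first.subjects or t.attributes != first.attributes:
            raise ValueError("tensors differ in subjects or attributes")
    pooled = np.mean([t.per_subject for t in tensors], axis=0)
    group = pooled.mean(axis=0)
    return DistanceTensor(
        first.subjects,
        first.attributes,
        pooled,
        group_matrix=group,
        n_imputations_pooled=len(tensors),
    )


def trajectory_summary(ds: PanelDataset) -> pd.DataFrame:
    """Observed-value mean and standard error per (attribute, timepoint).

    A descriptive group-level trajectory table (plot-ready); missing
    entries are excluded from each timepoint-specific mean.
    """
    rows = []
    for k, attr in enumerate(ds.attributes):
        for t in ds.timepoints:
            col = ds.values[:, t, k]
            obs = col[~np.isnan(col)]
            n = obs.size
            mean = float(obs.mean()) if n else np.nan
            se = float(obs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0 if n == 1 else np.nan
            rows.append(
                {"attribute": attr, "time": int(t), "n_observed": n, "mean": mean, "se": se}
            )
    return pd.DataFrame(rows)


def write_matrix_csv(matrix: np.ndarray, attributes: Sequence[str], path) -> None:
    """Square matrix as CSV with attributes as header row and column."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(np.asarray(matrix), index=list(attributes), columns=list(attributes)).to_csv(
        path, index_label="attribute"
    )


def read_matrix_csv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), tuple(df.columns)
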