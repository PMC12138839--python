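"""Directed lead-lag analysis: per-subject direction contrasts, group-level
edge tests, and out-/in-strength centralities with confidence intervals.

For an ordered attribute pair ``(a, b)`` the forward-only DTW distance
``D(a -> b)`` is small when a's changes align with same-time or later
values of b (a temporally leads b).  Because a raw DTW distance is always
nonnegative, the group-level quantity tested is the *direction contrast*

    delta(a -> b) = D(b -> a) - D(a -> b)

which is antisymmetric by construction; ``delta > 0`` means a's changes
precede b's.  Group-level significance uses a one-sided one-sample t-test
across subjects (a Wilcoxon signed-rank alternative is available); no
multiple-testing correction is applied by default, the node-level strength
tests being the main outcome family, with Bonferroni / Benjamini-Hochberg
available as options.

Out-strength of node j sums the positive parts of delta(j -> k) over the
other nodes (temporal lead); in-strength sums positive parts of
delta(k -> j) (temporal lag).  Strengths are standardized within subject
and kind by centering across the K nodes, so "significant" means above the
subject-average strength of the network; group estimates carry
t-distribution 95% CIs across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dtw import dtw_directed_batch
from .panel import PanelDataset

__all__ = [
    "DirectedDeltaTensor",
    "DirectedEdge",
    "StrengthEstimate",
    "directed_deltas",
    "pool_deltas",
    "test_directed_edges",
    "strength_centrality",
]


@dataclass(frozen=True)
class DirectedDeltaTensor:
    """Per-subject antisymmetric lead-lag matrices and group summaries.

    ``per_subject[s, a, b]`` is subject s's direction contrast
    ``delta(a -> b)``; ``group_mean``/``group_se`` are across-subject
    summaries.
    """

    subjects: tuple[str, ...]
    attributes: tuple[str, ...]
    per_subject: np.ndarray = field(repr=False)  # (S, K, K)
    group_mean: np.ndarray = field(default=None, repr=False)
    group_se: np.ndarray = field(default=None, repr=False)
    n_imputations_pooled: int = 1

    def __post_init__(self):
        ps = np.asarray(self.per_subject, dtype=float)
        s, k = len(self.subjects), len(self.attributes)
        if ps.shape != (s, k, k):
            raise ValueError(f"per_subject shape {ps.shape} != ({s}, {k}, {k})")
        if not np.allclose(ps, -ps.transpose(0, 2, 1), atol=1e-12):
            raise ValueError("per-subject delta matrices must be antisymmetric")
        object.__setattr__(self, "per_subject", ps)
        if self.group_mean is None:
            object.__setattr__(self, "group_mean", ps.mean(axis=0))
        if self.group_se is None:
            se = (
                ps.std(axis=0, ddof=1) / np.sqrt(s)
                if s > 1
                else np.zeros((k, k))
            )
            object.__setattr__(self, "group_se", se)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass(frozen=True)
class DirectedEdge:
    """Group-level test result for one ordered attribute pair."""

    source: str
    target: str
    mean_delta: float
    se: float
    statistic: float
    p_value: float
    significant: bool
    zero_variance: bool = False


@dataclass(frozen=True)
class StrengthEstimate:
    """Standardized out- or in-strength of one node with its 95% CI."""

    node: str
    kind: Literal["out", "in"]
    raw_mean: float
    standardized_mean: float
    ci_low: float
    ci_high: float
    significant: bool


def directed_deltas(ds: PanelDataset, max_lag: int = 1) -> DirectedDeltaTensor:
    """Per-subject direction contrasts for every ordered attribute pair.

    Requires complete, preprocessed data.  ``delta(a -> b) = D(b -> a) -
    D(a -> b)`` with D the forward-only DTW distance; positive values mean
    a's changes precede b's.
    """
    if not ds.is_complete():
        raise ValueError("dataset contains missing values; impute before DTW")
    s, _, k = ds.shape
    delta = np.zeros((s, k, k))
    for a in range(k):
        xa = ds.values[:, :, a]
        for b in range(a + 1, k):
            xb = ds.values[:, :, b]
            d_ab = dtw_directed_batch(xa, xb, max_lag)  # a leads b
            d_ba = dtw_directed_batch(xb, xa, max_lag)  # b leads a
            delta[:, a, b] = d_ba - d_ab
            delta[:, b, a] = -delta[:, a, b]
    return DirectedDeltaTensor(ds.subjects, ds.attributes, delta)


def pool_deltas(tensors: Sequence[DirectedDeltaTensor]) -> DirectedDeltaTensor:
    """Average per-subject deltas elementwise across imputation replicates,
    then recompute the group mean and SE across subjects."""
    if not tensors:
        raise ValueError("no tensors to pool")
    first = tensors[0]
    for t in tensors[1:]:
        if t.subjects != first.subjects or t.attributes != first.attributes:
            raise ValueError("tensors differ in subjects or attributes")
    pooled = np.mean([t.per_subject for t in tensors], axis=0)
    return DirectedDeltaTensor(
        first.subjects, first.attributes, pooled, n_imputations_pooled=len(tensors)
    )


def _one_sided_p(values: np.ndarray, method: str) -> tuple[float, float]:
    """(statistic, p) for H0: mean <= 0 vs H1: mean > 0 across subjects."""
    if method == "t":
        res = stats.ttest_1samp(values, 0.0, alternative="greater")
        return float(res.statistic), float(res.pvalue)
    if method == "wilcoxon":
        if np.all(values == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(values, alternative="greater", zero_method="wilcox")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test method {method!r}")


def test_directed_edges(
    tensor: DirectedDeltaTensor,
    alpha: float = 0.05,
    method: Literal["t", "wilcoxon"] = "t",
    correction: Optional[Literal["bonferroni", "bh"]] = None,
) -> list[DirectedEdge]:
    """One-sided group-level test of every ordered pair's mean delta.

    An edge a -> b is drawn when the across-subject mean of
    ``delta(a -> b)`` is significantly greater than zero; antisymmetry
    guarantees at most one direction per pair can be significant.  Returns
    results for *all* ordered pairs; filter on ``significant`` for the
    drawn edge set.

    Degenerate case: zero variance across subjects gives no t statistic;
    by convention a strictly positive constant mean is flagged significant
    (and marked ``zero_variance``), a nonpositive one is not.
    """
    if tensor.n_subjects < 3:
        raise ValueError("need at least 3 subjects for group-level tests")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    k = len(tensor.attributes)
    records = []
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            vals = tensor.per_subject[:, a, b]
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            se = sd / np.sqrt(tensor.n_subjects)
            if sd == 0.0:
                stat, p, zero_var = np.inf if mean > 0 else 0.0, (0.0 if mean > 0 else 1.0), True
            else:
                stat, p = _one_sided_p(vals, method)
                zero_var = False
            records.append((a, b, mean, se, stat, p, zero_var))

    pvals = np.array([r[5] for r in records])
    if correction is None:
        adjusted = pvals
    elif correction == "bonferroni":
        adjusted = np.minimum(pvals * len(pvals), 1.0)
    elif correction == "bh":
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests(pvals, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")

    edges = []
    for (a, b, mean, se, stat, p, zero_var), p_adj in zip(records, adjusted):
        edges.append(
            DirectedEdge(
                source=tensor.attributes[a],
                target=tensor.attributes[b],
                mean_delta=mean,
                se=float(se),
                statistic=stat,
                p_value=float(p_adj),
                significant=bool(p_adj < alpha),
                zero_variance=zero_var,
            )
        )
    return edges


def strength_centrality(tensor: DirectedDeltaTensor, ci_level: float = 0.95) -> list[StrengthEstimate]:
    """Standardized out-/in-strength per node with group-level CIs.

    Per subject: ``out(j) = sum_k max(delta(j -> k), 0)`` and ``in(j) =
    sum_k max(delta(k -> j), 0)``; each kind is centered across the K
    nodes within the subject (standardized strengths sum to zero per
    subject).  Group estimate: mean across subjects with a
    ``t_{1-(1-ci_level)/2, N-1}`` CI; significant when the CI excludes
    zero from below.
    """
    n = tensor.n_subjects
    if n < 3:
        raise ValueError("need at least 3 subjects for strength CIs")
    pos = np.maximum(tensor.per_subject, 0.0)  # (S, K, K)
    raw = {"out": pos.sum(axis=2), "in": pos.sum(axis=1)}  # each (S, K)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, df=n - 1)
    out: list[StrengthEstimate] = []
    for kind in ("out", "in"):
        r = raw[kind]
        std = r - r.mean(axis=1, keepdims=True)  # center across nodes per subject
        mean = std.mean(axis=0)
        se = std.std(axis=0, ddof=1) / np.sqrt(n)
        lo, hi = mean - tcrit * se, mean + tcrit * se
        for j, node in enumerate(tensor.attributes):
            out.append(
                StrengthEstimate(
                    node=node,
                    kind=kind,
                    raw_mean=float(r[:, j].mean()),
                    standardized_mean=float(mean[j]),
                    ci_low=float(lo[j]),
                    ci_high=float(hi[j]),
                    significant=bool(lo[j] > 0),
                )
            )
    return out


def edges_frame(edges: Sequence[DirectedEdge]) -> pd.DataFrame:
    """Directed edge table (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "mean_delta": e.mean_delta,
                "se": e.se,
                "t": e.statistic,
                "p": e.p_value,
                "significant": e.significant,
                "zero_variance": e.zero_variance,
            }
            for e in edges
        ]
    )


def strengths_frame(strengths: Sequence[StrengthEstimate]) -> pd.DataFrame:
    """Forest-plot table of strengths (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "node": s.node,
                "kind": s.kind,
                "raw_mean": s.raw_mean,
                "estimate": s.standardized_mean,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "significant": s.significant,
            }
            for s in strengths
        ]
    )
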