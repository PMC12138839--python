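"""Synthetic panel generator with known ground truth.

Emulates the statistical structure the network analysis assumes: clusters
of attributes sharing a latent within-person trajectory, optional planted
temporal precedence (one attribute whose changes lead others by one
assessment), large between-person level differences, inverted-valence
attributes, monotone dropout, and stacks of imputed replicates.

Generative model, per subject:

* each cluster c gets a latent AR(1) factor ``f_t = phi f_{t-1} + e_t``
  with standard-normal innovations and stationary initialisation
  (variance ``1 / (1 - phi^2)``);
* attribute value = subject intercept + loading * f_t + N(0, noise_sd);
* followers of a ``lead_spec`` read their cluster leader's factor lagged
  by one step (``follower_t`` tracks ``leader_{t-1}``), scaled by the
  coupling strength -- the lead is planted at the factor level, so the
  follower's first assessment reads the stationary pre-baseline factor
  rather than an edge artifact;
* subject intercepts are N(0, 2 * noise_sd + 1), creating the
  between-person heterogeneity that within-person centering must remove;
* reversed attributes are emitted negated (higher = better).

Everything is deterministic under the config seed.

The default configuration mirrors the eating-disorder cohort the pipeline
was designed around: 355 subjects, six assessments, the default
12-attribute schema grouped into its four empirical dimensions, dropout
hazard tuned to ~68% retention at the final assessment, and 100 imputed
replicates.  :func:`reference_config` is the smaller pinned configuration
used by the recovery test-bench, :func:`null_config` an
independent-attribute configuration for calibration checks.

The last-observation-carried-forward imputer here is a test double for a
real multiple-imputation model: it preserves the stack plumbing
(M complete replicates differing only stochastically) but not the
statistical properties of model-based imputation, and is not a
recommended way to impute real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .panel import PanelDataset
from .schema import AttributeSchema, default_schema

__all__ = [
    "LeadSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_panel",
    "apply_dropout",
    "naive_impute",
    "reference_config",
    "null_config",
]


@dataclass(frozen=True)
class LeadSpec:
    """Planted temporal precedence: followers track the leader's cluster
    factor one assessment later."""

    leader: str
    followers: tuple[str, ...]
    lag: int = 1
    coupling: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "followers", tuple(self.followers))
        if self.lag != 1:
            raise ValueError("only lag-1 precedence is supported")
        if not self.followers:
            raise ValueError("lead_spec needs at least one follower")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped defaults: N=355, T=6, four planted dimensions over the
    default 12-attribute schema, ~68% final retention, 100 imputations."""

    n_subjects: int = 355
    n_timepoints: int = 6
    clusters: tuple[tuple[str, ...], ...] = (
        ("depression", "anxiety", "ed_psychopathology", "quality_of_life", "self_rated_health"),
        ("social_support", "self_efficacy"),
        ("binge_eating", "vomiting"),
        ("bmi", "well_being", "laxative_use"),
    )
    factor_ar: float = 0.4
    loading: float = 1.0
    noise_sd: float = 0.5
    lead_spec: Optional[LeadSpec] = LeadSpec("social_support", ("self_efficacy",))
    reversed_attributes: tuple[str, ...] = (
        "bmi", "social_support", "self_efficacy", "well_being",
        "quality_of_life", "self_rated_health",
    )
    dropout_hazard: float = 0.074
    n_imputations: int = 100
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "clusters", tuple(tuple(c) for c in self.clusters))
        object.__setattr__(self, "reversed_attributes", tuple(self.reversed_attributes))
        names = [a for c in self.clusters for a in c]
        if len(set(names)) != len(names):
            raise ValueError("cluster attribute lists must be disjoint")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if not (0 <= self.factor_ar < 1):
            raise ValueError("factor_ar must be in [0, 1)")
        if self.loading <= 0:
            raise ValueError("loading must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.dropout_hazard < 1):
            raise ValueError("dropout_hazard must be in [0, 1)")
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if self.lead_spec is not None:
            missing = [
                a for a in (self.lead_spec.leader, *self.lead_spec.followers)
                if a not in names
            ]
            if missing:
                raise ValueError(f"lead_spec attributes not among clusters: {missing}")
        unknown_rev = set(self.reversed_attributes) - set(names)
        if unknown_rev:
            raise ValueError(f"reversed attributes not among clusters: {sorted(unknown_rev)}")

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(a for c in self.clusters for a in c)

    def schema(self) -> AttributeSchema:
        """Schema consistent with this config's attribute set and valences;
        uses the shipped study schema when the names match it."""
        base = default_schema()
        if set(self.attributes) <= set(base.names):
            return base
        from .schema import Attribute

        return AttributeSchema.from_attributes(
            [
                Attribute(a, higher_is_worse=a not in self.reversed_attributes)
                for a in self.attributes
            ]
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clusters"] = [list(c) for c in self.clusters]
        if self.lead_spec is not None:
            d["lead_spec"] = asdict(self.lead_spec)
            d["lead_spec"]["followers"] = list(self.lead_spec.followers)
        d["reversed_attributes"] = list(self.reversed_attributes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if d.get("lead_spec"):
            d["lead_spec"] = LeadSpec(**d["lead_spec"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    cluster_labels: dict[str, int]  # attribute -> 1-based cluster id
    leader: Optional[str]
    followers: tuple[str, ...]
    factors: np.ndarray = field(repr=False)  # (S, T + 1, C); column 0 is t = -1

    def labels_array(self, attributes: Sequence[str]) -> np.ndarray:
        return np.array([self.cluster_labels[a] for a in attributes])

    def to_manifest(self) -> dict:
        return {
            "cluster_labels": self.cluster_labels,
            "leader": self.leader,
            "followers": list(self.followers),
        }

    def write_manifest(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_manifest(), indent=2, sort_keys=True) + "\n")


def generate_panel(config: SyntheticConfig) -> tuple[PanelDataset, GroundTruth]:
    """Draw one complete panel dataset plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    s, t, phi = config.n_subjects, config.n_timepoints, config.factor_ar
    attrs = config.attributes
    n_clusters = len(config.clusters)

    # latent AR(1) factors, one per (subject, cluster), from t = -1 so a
    # lag-1 follower has a well-defined baseline value
    stat_sd = 1.0 / np.sqrt(1.0 - phi**2)
    factors = np.empty((s, t + 1, n_clusters))
    factors[:, 0, :] = rng.normal(0.0, stat_sd, size=(s, n_clusters))
    for step in range(1, t + 1):
        factors[:, step, :] = phi * factors[:, step - 1, :] + rng.normal(
            0.0, 1.0, size=(s, n_clusters)
        )

    intercept_sd = 2.0 * config.noise_sd + 1.0
    intercepts = rng.normal(0.0, intercept_sd, size=(s, len(attrs)))
    noise = rng.normal(0.0, config.noise_sd, size=(s, t, len(attrs)))

    cluster_of = {
        a: ci for ci, cluster in enumerate(config.clusters) for a in cluster
    }
    followers = set(config.lead_spec.followers) if config.lead_spec else set()
    leader_cluster = (
        cluster_of[config.lead_spec.leader] if config.lead_spec else None
    )

    values = np.empty((s, t, len(attrs)))
    for k, a in enumerate(attrs):
        if a in followers:
            signal = config.lead_spec.coupling * factors[:, 0:t, leader_cluster]
        else:
            signal = factors[:, 1 : t + 1, cluster_of[a]]
        values[:, :, k] = intercepts[:, [k]] + config.loading * signal + noise[:, :, k]
        if a in config.reversed_attributes:
            values[:, :, k] = -values[:, :, k]

    width = max(4, len(str(s)))
    subjects = tuple(f"S{i:0{width}d}" for i in range(1, s + 1))
    ds = PanelDataset(subjects, tuple(range(t)), attrs, values)
    truth = GroundTruth(
        cluster_labels={a: cluster_of[a] + 1 for a in attrs},
        leader=config.lead_spec.leader if config.lead_spec else None,
        followers=tuple(config.lead_spec.followers) if config.lead_spec else (),
        factors=factors,
    )
    return ds, truth


def apply_dropout(ds: PanelDataset, hazard: float, seed: int) -> PanelDataset:
    """Monotone dropout: each subject leaves at each post-baseline
    assessment with probability ``hazard``; after leaving, everything is
    missing.  Baseline is always observed, so expected retention at
    timepoint t is ``(1 - hazard)^t``."""
    if not (0 <= hazard < 1):
        raise ValueError("hazard must be in [0, 1)")
    rng = np.random.default_rng(seed)
    values = ds.values.copy()
    s, t, _ = ds.shape
    draws = rng.random((s, t - 1)) < hazard  # column j is the hazard at t = j+1
    for i in range(s):
        hit = np.nonzero(draws[i])[0]
        if hit.size:
            values[i, hit[0] + 1 :, :] = np.nan
    return ds.with_values(values)


def naive_impute(ds: PanelDataset, n_imputations: int, seed: int) -> list[PanelDataset]:
    """Last-observation-carried-forward imputation with stochastic
    perturbation -- a test double, not a recommended imputation method.

    Missing cells are filled with the subject's last observed value for
    that attribute plus N(0, sd) noise, where sd is the attribute's SD of
    observed one-step within-person changes.  Replicates differ only in
    the perturbations.  A missing cell with no earlier observed value (or
    a subject with no observed values at all for an attribute) is an
    error; monotone dropout with an observed baseline satisfies this.
    """
    if n_imputations < 1:
        raise ValueError("n_imputations must be >= 1")
    rng = np.random.default_rng(seed)
    s, t, k = ds.shape
    mask = ds.missing_mask()

    diffs = ds.values[:, 1:, :] - ds.values[:, :-1, :]
    resid_sd = np.empty(k)
    for j in range(k):
        obs = diffs[:, :, j][~np.isnan(diffs[:, :, j])]
        resid_sd[j] = float(obs.std(ddof=1)) if obs.size > 1 else 0.0

    # LOCF base fill (shared by all replicates)
    base = ds.values.copy()
    for i in range(s):
        for j in range(k):
            last = np.nan
            for tt in range(t):
                if np.isnan(base[i, tt, j]):
                    if np.isnan(last):
                        raise ValueError(
                            f"subject {ds.subjects[i]!r} has no observed value "
                            f"for {ds.attributes[j]!r} before t{tt}"
                        )
                    base[i, tt, j] = last
                else:
                    last = base[i, tt, j]

    out = []
    for m in range(1, n_imputations + 1):
        vals = base.copy()
        pert = rng.normal(0.0, 1.0, size=(s, t, k)) * resid_sd[None, None, :]
        vals[mask] += pert[mask]
        out.append(ds.with_values(vals, imputation_index=m))
    return out


def reference_config(seed: int = 1, **overrides) -> SyntheticConfig:
    """The pinned recovery-bench configuration: 12 attributes in planted
    clusters of sizes 5/2/2/3, one leader with coupling 1, N=300, T=6,
    phi=0.4, loading=1, noise_sd=0.5, complete data (no dropout, M=1)."""
    kwargs = dict(
        n_subjects=300,
        n_timepoints=6,
        factor_ar=0.4,
        loading=1.0,
        noise_sd=0.5,
        dropout_hazard=0.0,
        n_imputations=1,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def null_config(seed: int = 1, n_subjects: int = 100, n_attributes: int = 6) -> SyntheticConfig:
    """Independent attributes (singleton clusters), no planted lead -- the
    null configuration for directed-edge calibration."""
    names = tuple(f"attr{i:02d}" for i in range(1, n_attributes + 1))
    return SyntheticConfig(
        n_subjects=n_subjects,
        clusters=tuple((n,) for n in names),
        lead_spec=None,
        reversed_attributes=(),
        dropout_hazard=0.0,
        n_imputations=1,
        seed=seed,
    )
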