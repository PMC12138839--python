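"""Valence alignment, within-person centering and group-level standardization.

The pinned order of operations is reverse-code -> center -> standardize:

1. attributes scored "higher is better" are negated so higher always means
   worse;
2. each subject's own mean (over that subject's observed timepoints) is
   subtracted per attribute, removing between-person level differences so
   only within-person change drives the alignment distances;
3. each attribute's centered values are divided by the attribute's pooled
   standard deviation over all subjects and timepoints (population
   denominator ``n``), putting all attributes on a comparable
   within-person-change scale.

The SD denominator choice (``n`` vs ``n-1``) is a pure scale factor and
downstream results are invariant to it; ``n`` is pinned for determinism.
Missing values pass through untouched at every step.
"""

from __future__ import annotations

import numpy as np

from .panel import PanelDataset
from .schema import AttributeSchema

__all__ = [
    "reverse_code",
    "center_within_person",
    "standardize_group",
    "preprocess",
]


def reverse_code(ds: PanelDataset, schema: AttributeSchema) -> PanelDataset:
    """Negate attributes flagged ``higher_is_worse=False``; involution."""
    unknown = sorted(set(ds.attributes) - set(schema.names))
    if unknown:
        raise ValueError(f"attribute(s) not in schema: {unknown}")
    values = ds.values.copy()
    for k, name in enumerate(ds.attributes):
        if not schema[name].higher_is_worse:
            values[:, :, k] = -values[:, :, k]
    return ds.with_values(values, ds.imputation_index)


def center_within_person(ds: PanelDataset) -> PanelDataset:
    """Subtract each (subject, attribute) mean over its observed timepoints.

    Idempotent; a subject-attribute with no observed points stays
    all-missing.
    """
    values = ds.values.copy()
    with np.errstate(invalid="ignore"):
        person_mean = np.nanmean(values, axis=1, keepdims=True)  # (S, 1, K)
    person_mean = np.where(np.isnan(person_mean), 0.0, person_mean)
    return ds.with_values(values - person_mean, ds.imputation_index)


def standardize_group(ds: PanelDataset, *, rtol: float = 1e-12) -> PanelDataset:
    """Divide each attribute by its pooled SD over all subjects and timepoints.

    Expects already-centered input.  The SD uses the population denominator
    and only observed values.  An attribute with zero pooled variance
    cannot be standardized and raises, naming the attribute.
    """
    values = ds.values.copy()
    for k, name in enumerate(ds.attributes):
        col = values[:, :, k]
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            raise ValueError(f"attribute {name!r} has no observed values")
        sd = float(np.sqrt(np.mean((observed - observed.mean()) ** 2)))
        scale = max(abs(observed).max(), 1.0)
        if sd <= rtol * scale:
            raise ValueError(f"attribute {name!r} has zero group-level variance")
        values[:, :, k] = col / sd
    return ds.with_values(values, ds.imputation_index)


def preprocess(ds: PanelDataset, schema: AttributeSchema) -> PanelDataset:
    """Full pipeline: reverse-code, center within person, standardize."""
    return standardize_group(center_within_person(reverse_code(ds, schema)))
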