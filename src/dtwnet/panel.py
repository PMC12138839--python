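"""Panel (subject x timepoint x attribute) datasets and their file formats.

The in-memory container is :class:`PanelDataset`: a dense ``(S, T, K)``
float array with ``NaN`` marking missing values, plus ordered subject ids,
integer timepoint indices and attribute names.  Timepoints are assessment
indices ``0..T-1`` and are treated as consecutive; calendar spacing is the
caller's concern.

File formats
------------
* canonical long CSV: ``subject,time,attribute,value`` (missing written as
  the empty string, ``NA`` also accepted on read), rows sorted by
  (subject, time, attribute-order-in-schema);
* the same with an extra ``imputation`` column for stacks of complete
  imputed replicates;
* wide CSV convenience reader: ``subject,time,<attr1>,<attr2>,...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .schema import AttributeSchema

__all__ = [
    "PanelDataset",
    "PanelValidationReport",
    "read_long_csv",
    "read_wide_csv",
    "read_imputation_stack",
    "write_long_csv",
    "write_imputation_stack",
    "validate_panel",
]

MIN_TIMEPOINTS = 3
_MISSING_TOKENS = {"", "NA"}


def _parse_value(v) -> float:
    if v is None:
        return np.nan
    if isinstance(v, str):
        s = v.strip()
        return np.nan if s in _MISSING_TOKENS else float(s)
    return float(v)


@dataclass(frozen=True, eq=False)
class PanelDataset:
    """Rectangular panel of attribute values with an explicit missing marker.

    ``values[s, t, k]`` is the value for subject ``subjects[s]`` at
    assessment ``timepoints[t]`` on attribute ``attributes[k]``; missing is
    ``NaN``.  ``imputation_index`` (1-based) tags which replicate of an
    imputation stack this dataset is, if any.
    """

    subjects: tuple[str, ...]
    timepoints: tuple[int, ...]
    attributes: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    imputation_index: Optional[int] = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        s, t, k = len(self.subjects), len(self.timepoints), len(self.attributes)
        if vals.shape != (s, t, k):
            raise ValueError(f"values shape {vals.shape} != ({s}, {t}, {k})")
        if len(set(self.subjects)) != s:
            raise ValueError("duplicate subject ids")
        if len(set(self.attributes)) != k:
            raise ValueError("duplicate attribute names")
        if t < MIN_TIMEPOINTS:
            raise ValueError(
                f"at least {MIN_TIMEPOINTS} timepoints required, got {t}"
            )
        if tuple(self.timepoints) != tuple(range(t)):
            raise ValueError("timepoints must be consecutive integers starting at 0")
        if self.imputation_index is not None and self.imputation_index < 1:
            raise ValueError("imputation_index must be >= 1")
        vals.setflags(write=False)

    def __eq__(self, other) -> bool:
        """NaN-aware structural equality."""
        if not isinstance(other, PanelDataset):
            return NotImplemented
        return (
            self.subjects == other.subjects
            and self.timepoints == other.timepoints
            and self.attributes == other.attributes
            and self.imputation_index == other.imputation_index
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    # -- basic views ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.values))

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray, imputation_index=None) -> "PanelDataset":
        return replace(
            self, values=np.array(values, dtype=float), imputation_index=imputation_index
        )

    def attribute_index(self, name: str) -> int:
        try:
            return self.attributes.index(name)
        except ValueError:
            raise KeyError(f"unknown attribute {name!r}") from None

    def series(self, subject: str, attribute: str) -> np.ndarray:
        """One subject's trajectory on one attribute (may contain NaN)."""
        return self.values[self.subjects.index(subject), :, self.attribute_index(attribute)]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format frame in canonical row order (subject, time, attribute)."""
        s, t, k = self.shape
        df = pd.DataFrame(
            {
                "subject": np.repeat(self.subjects, t * k),
                "time": np.tile(np.repeat(self.timepoints, k), s),
                "attribute": np.tile(self.attributes, s * t),
                "value": self.values.reshape(-1),
            }
        )
        if self.imputation_index is not None:
            df.insert(0, "imputation", self.imputation_index)
        return df

    @classmethod
    def from_long_frame(
        cls,
        df: pd.DataFrame,
        schema: Optional[AttributeSchema] = None,
        imputation_index: Optional[int] = None,
    ) -> "PanelDataset":
        """Build from a long-format frame with subject/time/attribute/value columns.

        Subjects are ordered by sorted id, timepoints numerically, attributes
        in schema order (or sorted if no schema is given).  Unknown
        attributes and duplicate records are errors; (subject, time,
        attribute) cells absent from the frame are missing.
        """
        required = {"subject", "time", "attribute", "value"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValueError(f"missing required column(s): {sorted(missing_cols)}")
        df = df.copy()
        df["subject"] = df["subject"].astype(str)
        df["time"] = pd.to_numeric(df["time"], errors="raise").astype(int)
        df["attribute"] = df["attribute"].astype(str)
        # float() is correctly rounded, so written values reread bit-exactly
        # (pandas' fast to_numeric parser can be off by one ulp)
        df["value"] = df["value"].map(_parse_value)

        if schema is not None:
            unknown = sorted(set(df["attribute"]) - set(schema.names))
            if unknown:
                raise ValueError(f"attribute(s) not in schema: {unknown}")
            attributes = tuple(n for n in schema.names if n in set(df["attribute"]))
        else:
            attributes = tuple(sorted(df["attribute"].unique()))

        dup = df.duplicated(subset=["subject", "time", "attribute"])
        if dup.any():
            first = df.loc[dup, ["subject", "time", "attribute"]].iloc[0]
            raise ValueError(
                "duplicate record for "
                f"({first['subject']}, t{first['time']}, {first['attribute']})"
            )

        subjects = tuple(sorted(df["subject"].unique()))
        tmin, tmax = int(df["time"].min()), int(df["time"].max())
        if tmin != 0:
            raise ValueError("timepoint indices must start at 0")
        timepoints = tuple(range(tmax + 1))

        values = np.full((len(subjects), len(timepoints), len(attributes)), np.nan)
        sidx = {s: i for i, s in enumerate(subjects)}
        aidx = {a: i for i, a in enumerate(attributes)}
        values[
            df["subject"].map(sidx).to_numpy(),
            df["time"].to_numpy(),
            df["attribute"].map(aidx).to_numpy(),
        ] = df["value"].to_numpy()
        return cls(subjects, timepoints, attributes, values, imputation_index)


# ---------------------------------------------------------------------------
# readers / writers


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=sorted(_MISSING_TOKENS),
        encoding="utf-8",
    )


def read_long_csv(
    path,
    schema: Optional[AttributeSchema] = None,
    *,
    subject_col: str = "subject",
    time_col: str = "time",
    attribute_col: str = "attribute",
    value_col: str = "value",
) -> PanelDataset:
    """Read a long CSV (``subject,time,attribute,value``) into a validated panel."""
    df = _read_csv(path)
    rename = {subject_col: "subject", time_col: "time", attribute_col: "attribute", value_col: "value"}
    missing_cols = [c for c in rename if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required column(s): {missing_cols}")
    return PanelDataset.from_long_frame(df.rename(columns=rename), schema)


def read_wide_csv(path, schema: Optional[AttributeSchema] = None) -> PanelDataset:
    """Read a wide CSV (``subject,time,<attr>,...``), normalising to long form."""
    df = _read_csv(path)
    for col in ("subject", "time"):
        if col not in df.columns:
            raise ValueError(f"missing required column(s): ['{col}']")
    long = df.melt(id_vars=["subject", "time"], var_name="attribute", value_name="value")
    return PanelDataset.from_long_frame(long, schema)


def read_imputation_stack(
    path, schema: Optional[AttributeSchema] = None, *, imputation_col: str = "imputation"
) -> list[PanelDataset]:
    """Read a stacked long CSV of complete imputed replicates.

    The imputation column must hold contiguous indices ``1..M``; every
    replicate must be complete and all replicates must share subjects,
    timepoints and attributes.
    """
    df = _read_csv(path)
    if imputation_col not in df.columns:
        raise ValueError(f"missing required column(s): ['{imputation_col}']")
    df = df.rename(columns={imputation_col: "imputation"})
    indices = sorted(pd.to_numeric(df["imputation"], errors="raise").astype(int).unique())
    if indices != list(range(1, len(indices) + 1)):
        raise ValueError(f"non-contiguous imputation indices: {indices}")
    stack = []
    for m in indices:
        ds = PanelDataset.from_long_frame(
            df[df["imputation"].astype(int) == m].drop(columns=["imputation"]),
            schema,
            imputation_index=m,
        )
        if not ds.is_complete():
            raise ValueError(f"imputation replicate {m} contains missing values")
        stack.append(ds)
    shapes = {ds.shape for ds in stack}
    keys = {(ds.subjects, ds.timepoints, ds.attributes) for ds in stack}
    if len(shapes) > 1 or len(keys) > 1:
        raise ValueError("imputation replicates differ in subjects/timepoints/attributes")
    return stack


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["value"] = df["value"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    return df


def write_long_csv(ds: PanelDataset, path) -> None:
    """Write the canonical long CSV (UTF-8, comma, missing as empty string)."""
    df = _format_frame(ds.to_long_frame().drop(columns=["imputation"], errors="ignore"))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


def write_imputation_stack(stack: Sequence[PanelDataset], path) -> None:
    frames = []
    for m, ds in enumerate(stack, start=1):
        df = ds.to_long_frame().drop(columns=["imputation"], errors="ignore")
        df.insert(0, "imputation", m)
        frames.append(df)
    out = _format_frame(pd.concat(frames, ignore_index=True))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class PanelValidationReport:
    """Descriptive data-quality summary; never raises, never mutates."""

    n_subjects: int
    n_timepoints: int
    n_attributes: int
    missing_fraction_by_attribute: dict[str, float]
    retention_by_timepoint: dict[int, float]
    warnings: tuple[str, ...]

    @property
    def overall_missing_fraction(self) -> float:
        vals = list(self.missing_fraction_by_attribute.values())
        return float(np.mean(vals)) if vals else 0.0


def validate_panel(ds: PanelDataset) -> PanelValidationReport:
    """Report per-attribute missingness, per-timepoint retention and
    zero-variance attributes.

    Retention at timepoint ``t`` is the fraction of subjects with at least
    one observed attribute at ``t`` (a subject observed on nothing at ``t``
    has dropped out or skipped the assessment).
    """
    mask = ds.missing_mask()  # (S, T, K)
    miss_by_attr = {
        a: float(mask[:, :, k].mean()) for k, a in enumerate(ds.attributes)
    }
    retention = {
        int(t): float((~mask[:, t, :]).any(axis=1).mean()) for t in ds.timepoints
    }
    warnings = []
    for k, a in enumerate(ds.attributes):
        observed = ds.values[:, :, k][~mask[:, :, k]]
        if observed.size == 0:
            warnings.append(f"attribute {a!r} has no observed values")
        elif np.ptp(observed) == 0:
            warnings.append(f"attribute {a!r} has zero group-level variance")
    return PanelValidationReport(
        ds.n_subjects,
        ds.n_timepoints,
        ds.n_attributes,
        miss_by_attr,
        retention,
        tuple(warnings),
    )
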