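"""Panel readers/writers, schema handling and the validation report."""

import numpy as np
import pandas as pd
import pytest

from dtwnet import (
    AttributeSchema,
    PanelDataset,
    default_schema,
    read_imputation_stack,
    read_long_csv,
    read_wide_csv,
    validate_panel,
    write_imputation_stack,
    write_long_csv,
)


def long_csv(tmp_path, rows, header="subject,time,attribute,value"):
    path = tmp_path / "data.csv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


TWO_BY_THREE = [
    f"{s},{t},{a},{v}"
    for v, (s, t, a) in enumerate(
        (s, t, a) for s in ("s1", "s2") for t in (0, 1, 2) for a in ("attrA", "attrB")
    )
]


class TestLongReader:
    def test_complete_round(self, tmp_path):
        ds = read_long_csv(long_csv(tmp_path, TWO_BY_THREE))
        assert ds.shape == (2, 3, 2)
        assert ds.is_complete()
        assert ds.subjects == ("s1", "s2")
        assert ds.attributes == ("attrA", "attrB")

    def test_missing_cell_flagged(self, tmp_path):
        rows = list(TWO_BY_THREE)
        rows[0] = "s1,0,attrA,"
        ds = read_long_csv(long_csv(tmp_path, rows))
        assert int(ds.missing_mask().sum()) == 1
        assert np.isnan(ds.values[0, 0, 0])

    def test_na_token(self, tmp_path):
        rows = list(TWO_BY_THREE)
        rows[3] = "s1,1,attrB,NA"
        ds = read_long_csv(long_csv(tmp_path, rows))
        assert int(ds.missing_mask().sum()) == 1

    def test_duplicate_record_rejected(self, tmp_path):
        rows = TWO_BY_THREE + ["s1,0,attrA,9"]
        with pytest.raises(ValueError, match="duplicate record"):
            read_long_csv(long_csv(tmp_path, rows))

    def test_unknown_attribute_rejected(self, tmp_path, tiny_schema):
        with pytest.raises(ValueError, match="not in schema"):
            read_long_csv(long_csv(tmp_path, TWO_BY_THREE), tiny_schema)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject,time,value\ns1,0,1\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_long_csv(path)

    def test_too_few_timepoints_rejected(self, tmp_path):
        rows = [r for r in TWO_BY_THREE if ",2," not in r]
        with pytest.raises(ValueError, match="timepoints"):
            read_long_csv(long_csv(tmp_path, rows))

    def test_schema_orders_attributes(self, tmp_path):
        schema = AttributeSchema.from_names(["attrB", "attrA"])
        ds = read_long_csv(long_csv(tmp_path, TWO_BY_THREE), schema)
        assert ds.attributes == ("attrB", "attrA")


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, make_panel, rng):
        values = rng.standard_normal((3, 4, 2))
        values[0, 3, 1] = np.nan
        ds = make_panel(values)
        out = tmp_path / "roundtrip.csv"
        write_long_csv(ds, out)
        assert read_long_csv(out) == ds

    def test_wide_reader_matches_long(self, tmp_path, make_panel, rng):
        ds = make_panel(rng.standard_normal((2, 3, 2)))
        wide = tmp_path / "wide.csv"
        df = ds.to_long_frame().pivot_table(
            index=["subject", "time"], columns="attribute", values="value"
        ).reset_index()
        df.to_csv(wide, index=False)
        assert read_wide_csv(wide) == ds


class TestImputationStack:
    def _stack(self, make_panel, rng, m=3):
        return [
            make_panel(rng.standard_normal((2, 3, 2)), imputation_index=i + 1)
            for i in range(m)
        ]

    def test_round_trip(self, tmp_path, make_panel, rng):
        stack = self._stack(make_panel, rng)
        path = tmp_path / "stack.csv"
        write_imputation_stack(stack, path)
        back = read_imputation_stack(path)
        assert len(back) == 3
        assert all(a == b for a, b in zip(back, stack))

    def test_incomplete_replicate_rejected(self, tmp_path, make_panel, rng):
        stack = self._stack(make_panel, rng)
        vals = stack[1].values.copy()
        vals[0, 0, 0] = np.nan
        stack[1] = stack[1].with_values(vals, imputation_index=2)
        path = tmp_path / "stack.csv"
        write_imputation_stack(stack, path)
        with pytest.raises(ValueError, match="missing values"):
            read_imputation_stack(path)

    def test_non_contiguous_indices_rejected(self, tmp_path, make_panel, rng):
        stack = self._stack(make_panel, rng)
        path = tmp_path / "stack.csv"
        write_imputation_stack(stack, path)
        df = pd.read_csv(path)
        df.loc[df["imputation"] == 3, "imputation"] = 4
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="non-contiguous"):
            read_imputation_stack(path)


class TestValidation:
    def test_complete_data_full_retention(self, make_panel, rng):
        report = validate_panel(make_panel(rng.standard_normal((4, 3, 2))))
        assert all(v == 1.0 for v in report.retention_by_timepoint.values())
        assert report.overall_missing_fraction == 0.0
        assert report.warnings == ()

    def test_dropout_retention_counts(self, make_panel, rng):
        values = rng.standard_normal((5, 5, 2))
        values[0, 3:, :] = np.nan  # one of five subjects drops after t2
        report = validate_panel(make_panel(values))
        assert report.retention_by_timepoint[3] == pytest.approx(4 / 5)
        assert report.retention_by_timepoint[4] == pytest.approx(4 / 5)
        assert report.retention_by_timepoint[0] == 1.0

    def test_constant_attribute_warning(self, make_panel, rng):
        values = rng.standard_normal((3, 3, 2))
        values[:, :, 1] = 7.0
        report = validate_panel(make_panel(values))
        assert any("zero group-level variance" in w for w in report.warnings)


class TestSchema:
    def test_default_schema_shape_and_valences(self):
        schema = default_schema()
        assert len(schema) == 12
        assert set(schema.reversed_names()) == {
            "bmi", "social_support", "self_efficacy", "well_being",
            "quality_of_life", "self_rated_health",
        }

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            AttributeSchema.from_names(["a", "a"])

    def test_yaml_round_trip(self, tmp_path, tiny_schema):
        path = tmp_path / "schema.yaml"
        tiny_schema.to_file(path)
        assert AttributeSchema.from_file(path) == tiny_schema
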