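import numpy as np
import pandas as pd
import pytest

from nanoqsar import (
    ColumnSpec,
    DerivedRule,
    DescriptorSchema,
    fit_normaliser,
    load_dataset,
    recalc_derived,
    stratified_split,
    transform,
)
from nanoqsar.core_data import DataError, SchemaError

from conftest import make_table


class TestSchema:
    def test_rules_must_reference_existing_columns(self):
        with pytest.raises(SchemaError):
            DescriptorSchema(
                columns=[ColumnSpec("a", "numeric")],
                derived_rules=[DerivedRule("a", "difference", "a", "ghost")],
            )

    def test_derived_columns_cannot_chain(self):
        cols = [ColumnSpec(c, "numeric") for c in ("a", "b", "c")]
        with pytest.raises(SchemaError):
            DescriptorSchema(
                columns=cols,
                derived_rules=[
                    DerivedRule("b", "difference", "a", "c"),
                    DerivedRule("c", "difference", "a", "b"),
                ],
            )

    def test_yaml_round_trip(self, tiny_schema, tmp_path):
        path = tmp_path / "schema.yaml"
        tiny_schema.save(path)
        loaded = DescriptorSchema.load(path)
        assert loaded.to_dict() == tiny_schema.to_dict()


class TestLoadDataset:
    def test_fixture_round_trip(self, dataset, tmp_path):
        table, schema = dataset
        path = tmp_path / "data.csv"
        table.save(path)
        loaded = load_dataset(path, schema)
        assert len(loaded) == 110
        assert set(loaded.endpoint) == {"low", "high"}
        assert (loaded.data["provenance"] == "original").all()

    def test_empty_data_section_rejected(self, tiny_schema, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("treatment_id,a,b,d,endpoint\n")
        with pytest.raises(DataError, match="no treatments"):
            load_dataset(path, tiny_schema)

    def test_non_numeric_cell_names_row_and_column(self, tiny_schema, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "treatment_id,a,b,d,endpoint\nt0,1.0,2.0,-1.0,low\nt1,oops,2.0,-1.0,high\n"
        )
        with pytest.raises(DataError, match="'a', row 1"):
            load_dataset(path, tiny_schema)

    def test_duplicate_treatment_id_rejected(self, tiny_schema, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "treatment_id,a,b,d,endpoint\nt0,1,2,-1,low\nt0,3,4,-1,high\n"
        )
        with pytest.raises(DataError, match="duplicate treatment_id"):
            load_dataset(path, tiny_schema)


class TestStratifiedSplit:
    def test_reproduces_study_partition_sizes(self, dataset):
        # 110 rows (73 low / 37 high): 30% blind -> 33 (22/11); then 25%
        # of the remaining 77 -> 20 (13/7), train 57
        table, _ = dataset
        blind = stratified_split(table, 0.30, seed=5)
        assert len(blind.held_out) == 33
        assert blind.held_out.class_counts() == {"low": 22, "high": 11}
        tt = stratified_split(blind.train, 0.25, seed=6)
        assert len(tt.held_out) == 20
        assert tt.held_out.class_counts() == {"low": 13, "high": 7}
        assert len(tt.train) == 57

    def test_split_is_exact_partition(self, dataset):
        table, _ = dataset
        res = stratified_split(table, 0.30, seed=7)
        ids = sorted(res.train.data["treatment_id"]) + sorted(
            res.held_out.data["treatment_id"]
        )
        assert sorted(ids) == sorted(table.data["treatment_id"])

    @pytest.mark.parametrize("fraction", [0.1, 0.25, 0.3, 0.5])
    def test_class_proportions_within_one_count(self, dataset, fraction):
        table, _ = dataset
        res = stratified_split(table, fraction, seed=8)
        for label, count in table.class_counts().items():
            held = res.held_out.class_counts()[label]
            assert abs(held - fraction * count) <= 1

    def test_same_seed_gives_identical_partition(self, dataset):
        table, _ = dataset
        a = stratified_split(table, 0.30, seed=9)
        b = stratified_split(table, 0.30, seed=9)
        pd.testing.assert_frame_equal(a.held_out.data, b.held_out.data)

    def test_empty_train_class_rejected(self):
        t = make_table({"x": [1.0, 2.0, 3.0, 4.0]}, ["low", "low", "high", "high"])
        with pytest.raises(DataError):
            stratified_split(t, 0.9, seed=0)


class TestNormalisation:
    def test_closed_form_mean_sd(self):
        t = make_table({"x": [1.0, 2.0, 3.0]}, ["low", "high", "low"])
        params = fit_normaliser(t)
        assert params.mean["x"] == pytest.approx(2.0)
        assert params.sd["x"] == pytest.approx(1.0)

    def test_constant_column_flagged_and_passed_through(self):
        t = make_table({"x": [5.0, 5.0, 5.0]}, ["low", "high", "low"])
        params = fit_normaliser(t)
        assert params.zero_sd_columns == ["x"]
        fwd = transform(t, params, "forward")
        assert (fwd.data["x"] == 5.0).all()

    def test_training_columns_standardised(self, splits):
        train = splits["train"]
        params = fit_normaliser(train)
        z = transform(train, params, "forward")
        for col in params.columns:
            if params.sd[col] == 0:
                continue
            x = z.data[col].to_numpy(float)
            assert abs(x.mean()) < 1e-12
            assert abs(x.std(ddof=1) - 1) < 1e-12

    def test_round_trip_identity(self, splits):
        train = splits["train"]
        params = fit_normaliser(train)
        back = transform(transform(train, params, "forward"), params, "inverse")
        for col in params.columns:
            np.testing.assert_allclose(
                back.data[col].to_numpy(float),
                train.data[col].to_numpy(float),
                atol=1e-9,
            )

    def test_test_set_not_centred_by_training_params(self, splits):
        params = fit_normaliser(splits["train"])
        z = transform(splits["test"], params, "forward")
        means = [abs(z.data[c].to_numpy(float).mean()) for c in params.columns]
        assert max(means) > 1e-6  # training params do not centre other data

    def test_unknown_column_rejected(self, splits):
        params = fit_normaliser(splits["train"])
        extra = splits["test"].copy()
        params.mean["ghost"] = 0.0
        params.sd["ghost"] = 1.0
        with pytest.raises(DataError):
            transform(extra, params, "forward")


class TestRecalcDerived:
    def test_difference_rule(self, tiny_schema):
        t = make_table(
            {"a": [-5.0, 1.0], "b": [-3.0, 4.0], "d": [0.0, 0.0]}, ["low", "high"]
        )
        out = recalc_derived(t, tiny_schema)
        assert out.data["d"].tolist() == [-2.0, -3.0]

    def test_ratio_zero_denominator_flagged(self):
        schema = DescriptorSchema(
            columns=[ColumnSpec(c, "numeric") for c in ("a", "b", "r")],
            derived_rules=[DerivedRule("r", "ratio", "a", "b")],
        )
        t = make_table(
            {"a": [1.0, 2.0], "b": [2.0, 0.0], "r": [0.0, 0.0]}, ["low", "high"]
        )
        with pytest.warns(UserWarning, match="zero denominator"):
            out = recalc_derived(t, schema)
        assert out.data["r"].iloc[0] == pytest.approx(0.5)
        assert np.isnan(out.data["r"].iloc[1])

    def test_generated_rows_satisfy_rules(self, dataset):
        table, schema = dataset
        recalced = recalc_derived(table, schema)
        for rule in schema.derived_rules:
            np.testing.assert_allclose(
                recalced.data[rule.target], table.data[rule.target], rtol=1e-9
            )
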