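import numpy as np
import pytest

from nanoqsar import preprocess
from nanoqsar.preprocessing import (
    apply_preprocessing,
    dedupe,
    information_gain,
    information_gain_filter,
    spearman_filter,
    variance_filter,
)

from conftest import make_table


class TestVarianceFilter:
    def test_constant_column_dropped(self):
        t = make_table({"c": [1.0] * 4, "x": [0.0, 5.0, 10.0, 15.0]},
                       ["low", "low", "high", "high"])
        kept, dropped = variance_filter(t, threshold=0.2)
        assert kept == ["x"]
        assert dropped == [("c", 0.0)]

    def test_binary_column_kept_at_study_threshold(self):
        # sample variance of [0,1,0,1] is 1/3 >= 0.2
        t = make_table({"x": [0.0, 1.0, 0.0, 1.0]}, ["low", "high", "low", "high"])
        kept, _ = variance_filter(t, threshold=0.2)
        assert kept == ["x"]

    def test_zero_threshold_only_drops_exact_constants(self):
        t = make_table(
            {"c": [2.0] * 4, "x": [0.0, 0.001, 0.0, 0.001]},
            ["low", "low", "high", "high"],
        )
        kept, _ = variance_filter(t, threshold=0.0)
        assert kept == ["x"]

    def test_categorical_exempt(self):
        t = make_table({"cat": ["a", "a", "a", "a"]}, ["low", "low", "high", "high"])
        kept, _ = variance_filter(t, threshold=0.2, categorical={"cat"})
        assert kept == ["cat"]


class TestSpearmanFilter:
    def test_monotone_transform_detected(self):
        x = np.linspace(-2, 2, 20)
        t = make_table({"x": x, "y": x**3}, ["low"] * 10 + ["high"] * 10)
        kept, dropped = spearman_filter(t, threshold=0.95)
        assert kept == ["x"]
        assert dropped[0][:2] == ("x", "y")
        assert dropped[0][2] == pytest.approx(1.0)

    def test_duplicate_pair_keeps_exactly_one(self):
        x = np.arange(10.0)
        t = make_table({"a": x, "b": x.copy()}, ["low"] * 5 + ["high"] * 5)
        kept, _ = spearman_filter(t, threshold=0.95)
        assert kept == ["a"]

    def test_independent_noise_survives(self):
        rng = np.random.default_rng(31)
        cols = {f"n{i}": rng.normal(size=200) for i in range(6)}
        t = make_table(cols, ["low"] * 100 + ["high"] * 100)
        kept, dropped = spearman_filter(t, threshold=0.95)
        assert dropped == []
        assert kept == list(cols)

    def test_greedy_scan_uses_schema_order(self):
        # b correlates with a (kept first); c correlates only with b.
        # After b is dropped, c must survive: dropped columns cannot
        # cause further drops.
        x = np.arange(20.0)
        rng = np.random.default_rng(32)
        noise = rng.normal(scale=20.0, size=20)
        t = make_table(
            {"a": x, "b": x + 0.001 * noise, "c": -(x + 0.001 * noise)},
            ["low"] * 10 + ["high"] * 10,
        )
        kept, dropped = spearman_filter(t, threshold=0.95)
        assert "a" in kept
        assert [d[1] for d in dropped] == ["b", "c"]


class TestInformationGain:
    def test_constant_column_zero_gain(self):
        t = make_table({"c": [3.0] * 4}, ["low", "low", "high", "high"])
        kept, scores = information_gain_filter(t)
        assert scores["c"] == pytest.approx(0.0, abs=1e-12)
        assert kept == []

    def test_perfect_predictor_one_bit(self):
        t = make_table({"x": [0.0, 0.0, 1.0, 1.0]}, ["low", "low", "high", "high"])
        scores = information_gain(t)
        assert scores["x"] == pytest.approx(1.0)

    def test_hand_computed_partial_gain(self):
        # endpoint (1,1,0,0), bins (A,A,A,B): IG = 1 - 0.75*H(2/3, 1/3)
        t = make_table({"g": ["A", "A", "A", "B"]}, ["high", "high", "low", "low"])
        scores = information_gain(t, categorical={"g"})
        expected = 1.0 - 0.75 * (-(2 / 3) * np.log2(2 / 3) - (1 / 3) * np.log2(1 / 3))
        assert scores["g"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3113, abs=5e-5)


class TestDedupe:
    def test_identical_rows_collapse(self):
        t = make_table({"x": [1.0, 1.0, 2.0]}, ["low", "low", "high"])
        out, removed = dedupe(t, ["x"])
        assert len(out) == 2
        assert removed == 1

    def test_conflicting_endpoints_retained_with_warning(self):
        t = make_table({"x": [1.0, 1.0]}, ["low", "high"])
        with pytest.warns(UserWarning, match="conflicting"):
            out, removed = dedupe(t, ["x"])
        assert len(out) == 2
        assert removed == 0


class TestPreprocessCascade:
    def test_planted_signal_in_top_three_gain_scores(self, dataset):
        table, schema = dataset
        res = preprocess(table, schema)
        top3 = list(res.trace.ig_scores)[:3]
        assert "concentration" in top3

    def test_selected_columns_all_have_positive_gain(self, dataset):
        table, schema = dataset
        res = preprocess(table, schema)
        assert res.trace.selected
        for col in res.trace.selected:
            assert res.trace.ig_scores[col] > 0

    def test_output_standardised(self, dataset):
        table, schema = dataset
        res = preprocess(table, schema)
        for col in res.params.columns:
            if res.params.sd[col] == 0:
                continue
            x = res.table.data[col].to_numpy(float)
            assert abs(x.mean()) < 1e-10
            assert abs(x.std(ddof=1) - 1) < 1e-10

    def test_variance_filter_runs_before_spearman(self):
        # lowvar (schema-first, tiny variance) correlates perfectly with
        # highvar.  Variance-first drops lowvar and keeps highvar; a
        # Spearman-first order would instead discard highvar as the
        # later redundant column.
        from nanoqsar import ColumnSpec, DescriptorSchema

        x = np.arange(30.0)
        schema = DescriptorSchema(
            columns=[ColumnSpec("lowvar", "numeric"), ColumnSpec("highvar", "numeric")]
        )
        t = make_table(
            {"lowvar": 1e-4 * x, "highvar": 10.0 * x}, ["low"] * 15 + ["high"] * 15
        )
        res = preprocess(t, schema)
        assert "highvar" in res.trace.selected
        assert "lowvar" not in res.trace.selected
        assert [c for c, _ in res.trace.dropped_low_variance] == ["lowvar"]
        assert res.trace.dropped_correlated == []

    def test_frozen_selection_replayed_on_new_data(self, dataset, splits):
        _, schema = dataset
        res = preprocess(splits["train"], schema)
        replayed = apply_preprocessing(splits["test"], res.trace.selected, res.params)
        assert replayed.descriptor_columns == res.trace.selected
        assert len(replayed) == len(splits["test"])
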