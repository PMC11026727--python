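import numpy as np
import pandas as pd
import pytest

from nanoqsar import (
    OversampleConfig,
    adasyn,
    fit_normaliser,
    oversample_pipeline,
    smote,
    stratified_split,
    transform,
)
from nanoqsar._rng import child_rng

from conftest import make_table


@pytest.fixture(scope="module")
def train_57(dataset):
    table, _ = dataset
    rest = stratified_split(table, 0.30, seed=11).train
    return stratified_split(rest, 0.25, seed=12).train


class TestSmote:
    def test_balances_classes_exactly(self, train_57):
        # 57 rows (38 low / 19 high) -> 76 rows, 38/38
        params = fit_normaliser(train_57)
        z = transform(train_57, params, "forward")
        out = smote(z, OversampleConfig(method="smote", seed=5))
        assert len(out) == 76
        assert out.class_counts() == {"low": 38, "high": 38}
        assert (out.data["provenance"] == "synthetic").sum() == 19

    def test_identical_minority_points_reproduce_themselves(self):
        t = make_table(
            {"x": [0.0, 0.0, 1.0, 2.0, 3.0, 4.0]},
            ["high", "high", "low", "low", "low", "low"],
        )
        out = smote(t, OversampleConfig(method="smote", k_neighbours=1, seed=6))
        synth = out.data[out.data["provenance"] == "synthetic"]
        assert (synth["x"] == 0.0).all()

    def test_one_dimensional_interpolation_matches_rng_replay(self):
        # independent oracle: replay the named child RNG stream and place
        # the points on the segment by hand
        t = make_table(
            {"x": [0.0, 10.0, 1.0, 2.0, 3.0, 4.0]},
            ["high", "high", "low", "low", "low", "low"],
        )
        seed = 7
        out = smote(t, OversampleConfig(method="smote", k_neighbours=1, seed=seed))
        synth = out.data[out.data["provenance"] == "synthetic"]["x"].to_numpy()
        rng = child_rng(seed, "smote")
        base = rng.integers(0, 2, size=2)
        rng.integers(0, 1, size=2)  # neighbour pick (only one neighbour)
        u = rng.random(2)
        x_min = np.array([0.0, 10.0])
        expected = x_min[base] + u * (x_min[1 - base] - x_min[base])
        np.testing.assert_allclose(synth, expected)

    def test_synthetic_points_are_convex_combinations(self, train_57):
        params = fit_normaliser(train_57)
        z = transform(train_57, params, "forward")
        cfg = OversampleConfig(method="smote", seed=8)
        out = smote(z, cfg)
        cols = z.descriptor_columns
        minority = z.data[z.data["endpoint"] == "high"][cols].to_numpy(float)
        synth = out.data[out.data["provenance"] == "synthetic"][cols].to_numpy(float)
        # replay the stream to recover each synthetic row's segment
        rng = child_rng(cfg.seed, "smote")
        n_new = len(synth)
        base = rng.integers(0, len(minority), size=n_new)
        rng.integers(0, cfg.k_neighbours, size=n_new)
        rng.random(n_new)
        from nanoqsar.oversampling import _knn_indices

        nn = _knn_indices(minority, minority, cfg.k_neighbours, exclude_self=True)
        for j in range(n_new):
            seg = minority[[base[j], *nn[base[j]]]]
            lo = seg.min(axis=0) - 1e-12
            hi = seg.max(axis=0) + 1e-12
            assert np.all(synth[j] >= lo) and np.all(synth[j] <= hi)

    def test_k_clamped_with_warning(self):
        t = make_table(
            {"x": [0.0, 1.0, 5.0, 6.0, 7.0, 8.0]},
            ["high", "high", "low", "low", "low", "low"],
        )
        with pytest.warns(UserWarning, match="clamped"):
            out = smote(t, OversampleConfig(method="smote", k_neighbours=5, seed=9))
        assert out.class_counts() == {"low": 4, "high": 4}


class TestAdasyn:
    def test_boundary_minority_row_receives_all_synthetics(self):
        # one minority row sits among the majority (r = 1), the other
        # three form a far-away cluster whose k nearest neighbours are
        # all minority (r = 0): the whole budget G goes to the first
        t = make_table(
            {"x": [0.0, 100.0, 101.0, 102.0, -0.5, 0.5, -1.0, 1.0, -2.0, 2.0]},
            ["high", "high", "high", "high"] + ["low"] * 6,
        )
        out = adasyn(t, OversampleConfig(method="adasyn", k_neighbours=2, seed=10))
        synth = out.data[out.data["provenance"] == "synthetic"]
        assert len(synth) == 2  # G = 6 - 4
        # synthetics seeded at x=0 interpolate toward minority neighbours
        assert (synth["np_id"] == "t0").all()

    def test_isolated_minority_cluster_receives_none(self):
        t = make_table(
            {"x": [0.0, 100.0, 100.5, 101.0, -0.5, 0.5, -1.0, 1.0, -2.0, 2.0]},
            ["high", "high", "high", "high"] + ["low"] * 6,
        )
        out = adasyn(t, OversampleConfig(method="adasyn", k_neighbours=2, seed=11))
        synth = out.data[out.data["provenance"] == "synthetic"]
        assert not (synth["np_id"].isin(["t1", "t2", "t3"])).any()

    def test_uniform_fallback_when_no_majority_neighbours(self):
        # minority cluster so tight that no minority row sees a majority
        # neighbour among its k nearest
        t = make_table(
            {"x": [0.0, 0.1, 0.2, 50.0, 51.0, 52.0, 53.0, 54.0]},
            ["high", "high", "high", "low", "low", "low", "low", "low"],
        )
        with pytest.warns(UserWarning, match="uniform"):
            out = adasyn(t, OversampleConfig(method="adasyn", k_neighbours=2, seed=12))
        assert out.class_counts() == {"low": 5, "high": 5}

    def test_fixture_counts_near_balance(self, train_57):
        params = fit_normaliser(train_57)
        z = transform(train_57, params, "forward")
        out = adasyn(z, OversampleConfig(method="adasyn", seed=13))
        assert abs(len(out) - 76) <= 1
        assert (out.data["endpoint"] == "low").sum() == 38


class TestOversamplePipeline:
    @pytest.mark.parametrize("method", ["smote", "adasyn"])
    def test_original_rows_bit_identical(self, train_57, dataset, method):
        _, schema = dataset
        out = oversample_pipeline(
            train_57, schema, OversampleConfig(method=method, seed=14)
        )
        orig = out.data[out.data["provenance"] == "original"].reset_index(drop=True)
        pd.testing.assert_frame_equal(orig, train_57.data)

    @pytest.mark.parametrize("method", ["smote", "adasyn"])
    def test_synthetic_rows_satisfy_derived_rules_exactly(
        self, train_57, dataset, method
    ):
        _, schema = dataset
        out = oversample_pipeline(
            train_57, schema, OversampleConfig(method=method, seed=15)
        )
        synth = out.data[out.data["provenance"] == "synthetic"]
        for rule in schema.derived_rules:
            expected = rule.evaluate(
                synth[rule.a].to_numpy(float), synth[rule.b].to_numpy(float)
            )
            np.testing.assert_array_equal(synth[rule.target].to_numpy(float), expected)

    def test_majority_class_untouched(self, train_57, dataset):
        _, schema = dataset
        out = oversample_pipeline(
            train_57, schema, OversampleConfig(method="smote", seed=16)
        )
        assert (out.data["endpoint"] == "low").sum() == 38
        assert (
            out.data.loc[out.data["provenance"] == "synthetic", "endpoint"] == "high"
        ).all()

    def test_balance_within_one_row(self, train_57, dataset):
        _, schema = dataset
        for method in ("smote", "adasyn"):
            out = oversample_pipeline(
                train_57, schema, OversampleConfig(method=method, seed=17)
            )
            counts = out.class_counts()
            assert abs(counts["low"] - counts["high"]) <= 1

    def test_deterministic_given_seed(self, train_57, dataset):
        _, schema = dataset
        cfg = OversampleConfig(method="adasyn", seed=18)
        a = oversample_pipeline(train_57, schema, cfg)
        b = oversample_pipeline(train_57, schema, cfg)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_missing_value_columns_excluded(self, train_57, dataset):
        _, schema = dataset
        broken = train_57.copy()
        broken.data.loc[0, "desc_02"] = np.nan
        out = oversample_pipeline(
            broken, schema, OversampleConfig(method="smote", seed=19)
        )
        assert "desc_02" not in out.data.columns
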