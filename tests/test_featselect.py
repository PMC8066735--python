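import numpy as np
import pandas as pd
import pytest

from plantloc.featselect import (
    CFSGeneticSelector,
    OneRSelector,
    ReliefFSelector,
    SelectionResult,
    cfs_ga_search,
    cfs_merit,
    equal_frequency_bins,
    oner_rank,
    relieff,
    select_top,
    symmetric_uncertainty,
)


def toy_table(n=200, seed=0, n_noise=7):
    """3 informative features (class-shifted) + pure-noise features, 2 classes."""
    rng = np.random.default_rng(seed)
    y = np.tile(["a", "b"], n // 2)
    cols = {}
    for j in range(3):
        shift = (y == "b").astype(float) * 2.0
        cols[f"inf{j}"] = shift + 0.3 * rng.standard_normal(n)
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.standard_normal(n)
    return pd.DataFrame(cols), y


class TestReliefF:
    def test_constant_feature_weight_zero(self):
        X, y = toy_table()
        X["const"] = 3.14
        res = relieff(X, y, seed=1)
        assert res.weights["const"] == 0.0

    def test_informative_beats_noise(self):
        for seed in range(10):
            X, y = toy_table(seed=seed)
            res = relieff(X, y, seed=seed)
            assert res.weights["inf0"] > res.weights["noise0"]

    def test_label_encoding_feature_is_maximal(self):
        X, y = toy_table(seed=3)
        X["encode"] = (y == "b").astype(float)
        res = relieff(X, y, seed=3)
        assert max(res.weights, key=res.weights.get) == "encode"

    def test_hand_computed_margin(self):
        # 4 rows, 2 features already spanning [0,1]; k=1, all rows sampled.
        # Per row: subtract the near-hit diff, add the near-miss diff
        # (balanced classes, so the miss prior weight is 1); ties go to the
        # lower row index.
        X = pd.DataFrame({"f1": [0.0, 0.2, 1.0, 0.8], "f2": [0.0, 1.0, 0.5, 0.4]})
        y = np.array(["a", "a", "b", "b"])
        sel = ReliefFSelector(n_features=2, k_neighbors=1).fit(X, y)
        # r0: hit r1 (.2,1.0), miss r3 (.8,.4); r1: hit r0, miss r3 (.6,.6)
        # r2: hit r3 (.2,.1), miss r1 (.8,.5); r3: hit r2, miss r0 (.8,.4)
        expected = np.array(
            [(0.6 + 0.4 + 0.6 + 0.6) / 4, (-0.6 - 0.4 + 0.4 + 0.3) / 4]
        )
        assert np.allclose(sel.scores_, expected)

    def test_small_class_reduces_k_with_warning(self):
        X = pd.DataFrame({"f": [0.0, 0.1, 1.0]})
        y = np.array(["a", "a", "b"])
        with pytest.warns(UserWarning, match="reduced"):
            ReliefFSelector(n_features=1, k_neighbors=5).fit(X, y)

    def test_weights_bounded(self):
        X, y = toy_table(seed=5)
        res = relieff(X, y, seed=5)
        assert all(-1.0 <= w <= 1.0 for w in res.weights.values())

    def test_deterministic(self):
        X, y = toy_table(seed=6)
        a = ReliefFSelector(seed=9, n_samples=50).fit(X, y).scores_
        b = ReliefFSelector(seed=9, n_samples=50).fit(X, y).scores_
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        X, _ = toy_table()
        with pytest.raises(ValueError, match="2 classes"):
            relieff(X, np.repeat("a", len(X)))


class TestOneR:
    def test_label_encoding_scores_one(self):
        X, y = toy_table(seed=1)
        X["encode"] = (y == "b").astype(float)
        res = oner_rank(X, y)
        assert res.weights["encode"] == 1.0

    def test_independent_feature_near_chance(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"f": rng.standard_normal(10000)})
        y = np.repeat(["a", "b"], 5000)
        res = oner_rank(X, y)
        assert res.weights["f"] == pytest.approx(0.5, abs=0.03)

    def test_constant_feature_majority_rule(self):
        X = pd.DataFrame({"f": np.zeros(110)})
        y = np.repeat([str(i) for i in range(11)], 10)
        res = oner_rank(X, y)
        assert res.weights["f"] == pytest.approx(1 / 11, abs=1e-9)

    def test_low_cardinality_uses_distinct_bins(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0])
        assert len(np.unique(equal_frequency_bins(x, n_bins=10))) == 3


class TestCFS:
    def test_singleton_merit_is_class_correlation(self):
        X, y = toy_table(seed=2)
        codes = equal_frequency_bins(X["inf0"].to_numpy())
        y_codes = np.unique(y, return_inverse=True)[1]
        assert cfs_merit(["inf0"], X, y) == pytest.approx(
            symmetric_uncertainty(codes, y_codes)
        )

    def test_exact_duplicate_pair_not_better_than_singleton(self):
        # with r_ff = 1 and equal r_cf the merit formula collapses to r_cf:
        # a perfectly redundant copy buys nothing
        X, y = toy_table(seed=2)
        X["copy"] = X["inf0"]
        single = cfs_merit(["inf0"], X, y)
        pair = cfs_merit(["inf0", "copy"], X, y)
        assert pair == pytest.approx(single, abs=1e-12)

    def test_irrelevant_addition_strictly_lowers_merit(self):
        X, y = toy_table(seed=2)
        assert cfs_merit(["inf0", "noise0"], X, y) < cfs_merit(["inf0"], X, y)

    def test_independent_informative_pair_beats_singletons(self):
        X, y = toy_table(seed=4)
        pair = cfs_merit(["inf0", "inf1"], X, y)
        assert pair > cfs_merit(["inf0"], X, y)
        assert pair > cfs_merit(["inf1"], X, y)

    def test_zero_variance_contributes_zero(self):
        X, y = toy_table(seed=2)
        X["const"] = 1.0
        assert cfs_merit(["const"], X, y) == 0.0


class TestCFSGA:
    def test_recovers_informative_features(self):
        hits = 0
        for seed in range(10):
            X, y = toy_table(seed=seed)
            res = cfs_ga_search(X, y, generations=50, seed=seed)
            if {"inf0", "inf1", "inf2"} <= set(res.selected):
                hits += 1
        assert hits >= 9

    def test_zero_generations_reproducible(self):
        X, y = toy_table(seed=3)
        a = cfs_ga_search(X, y, generations=0, seed=5)
        b = cfs_ga_search(X, y, generations=0, seed=5)
        assert a.selected == b.selected and a.params["merit"] == b.params["merit"]

    def test_returned_merit_consistent(self):
        X, y = toy_table(seed=3)
        res = cfs_ga_search(X, y, generations=20, seed=5)
        assert res.params["merit"] == pytest.approx(cfs_merit(res.selected, X, y))

    def test_elitism_merit_nondecreasing(self):
        X, y = toy_table(seed=3)
        sel = CFSGeneticSelector(generations=30, seed=2).fit(X, y)
        assert all(b >= a - 1e-12 for a, b in zip(sel.merit_history_, sel.merit_history_[1:]))


class TestSelectTop:
    def _result(self, weights):
        return SelectionResult("oner", weights, list(weights), {})

    def test_tie_broken_by_schema_order(self):
        res = self._result({"w": 0.9, "x": 0.5, "y": 0.5, "z": 0.1})
        assert select_top(res, 2).selected == ["w", "x"]

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            select_top(self._result({"a": 1.0}), 0)

    def test_n_equal_total_is_identity(self):
        res = self._result({"a": 0.3, "b": 0.2})
        assert set(select_top(res, 2).selected) == {"a", "b"}

    def test_overlarge_n_warns(self):
        with pytest.warns(UserWarning):
            out = select_top(self._result({"a": 0.3}), 5)
        assert out.selected == ["a"]

    def test_json_roundtrip(self):
        res = select_top(self._result({"a": 0.3, "b": 0.2}), 1)
        back = SelectionResult.from_json(res.to_json())
        assert back.selected == res.selected and back.method == res.method


class TestSelectorEstimators:
    def test_transform_keeps_selected_columns(self):
        X, y = toy_table(seed=8)
        sel = OneRSelector(n_features=3).fit(X, y)
        assert sel.transform(X).shape == (len(X), 3)

    def test_training_partition_only_interface(self):
        # selector state depends only on what fit() saw
        X, y = toy_table(seed=8)
        a = ReliefFSelector(seed=0).fit(X.iloc[:100], y[:100]).scores_
        b = ReliefFSelector(seed=0).fit(X.iloc[:100], y[:100]).scores_
        assert np.array_equal(a, b)
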