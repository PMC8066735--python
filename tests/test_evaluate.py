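import numpy as np
import pandas as pd
import pytest

import oracles
from plantloc.evaluate import (
    ConfusionCounts,
    binary_metrics,
    combined_accuracy,
    cross_validate,
    multiclass_report,
    pcc_feature_analysis,
    roc_auc,
)
from plantloc.ensemble import LocalizationEnsemble


class TestBinaryMetrics:
    def test_perfect_small_class(self):
        # 5 positives all recovered against 624 negatives
        acc, sn, sp, mcc = binary_metrics(ConfusionCounts(TP=5, TN=624, FP=0, FN=0))
        assert (sn, sp, mcc) == (1.0, 1.0, 1.0)

    def test_balanced_random_is_zero(self):
        *_, mcc = binary_metrics(ConfusionCounts(TP=25, TN=25, FP=25, FN=25))
        assert mcc == 0.0

    def test_half_sensitivity_case(self):
        acc, sn, sp, mcc = binary_metrics(ConfusionCounts(TP=3, TN=623, FP=0, FN=3))
        assert sn == pytest.approx(0.5)
        assert mcc == pytest.approx(3 * 623 / np.sqrt(3 * 6 * 623 * 626), rel=1e-9)
        assert mcc == pytest.approx(0.7054, abs=5e-4)

    def test_zero_denominator_convention(self):
        *_, mcc = binary_metrics(ConfusionCounts(TP=0, TN=10, FP=0, FN=0))
        assert mcc == 0.0

    def test_matches_bruteforce_on_random_tuples(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + tn + fp + fn == 0:
                continue
            got = binary_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            exp = oracles.binary_metrics_oracle(int(tp), int(tn), int(fp), int(fn))
            for g, e in zip(got, exp):
                assert g == pytest.approx(e, nan_ok=True)


class TestMulticlassReport:
    def test_all_correct(self):
        truth = ["nucleus", "plastid", {"cytoplasm", "nucleus"}]
        rep = multiclass_report(truth, truth)
        assert rep.overall_acc == 1.0
        assert (rep.per_class.loc[["nucleus", "plastid"], "MCC"] == 1.0).all()

    def test_partial_dual_match_is_incorrect(self):
        rep = multiclass_report([{"cytoplasm", "nucleus"}], [{"cytoplasm"}])
        assert rep.overall_acc == 0.0 and rep.multi_acc == 0.0

    def test_dual_record_counts_positive_for_both_classes(self):
        rep = multiclass_report([{"cytoplasm", "nucleus"}], [{"cytoplasm", "nucleus"}])
        assert rep.per_class.loc["cytoplasm", "TP"] == 1
        assert rep.per_class.loc["nucleus", "TP"] == 1

    def test_combined_accuracy_from_subtotals(self):
        # 506/592 single + 26/37 dual pool to 532/629 = 84.58%
        acc = combined_accuracy(592, 506, 37, 26)
        assert acc == pytest.approx(532 / 629)
        assert round(100 * acc, 2) == 84.58

    def test_overall_equals_weighted_subtotals(self, rng):
        classes = ["nucleus", "plastid", "golgi"]
        truth = [
            {rng.choice(classes)} if rng.random() < 0.8
            else {"cytoplasm", rng.choice(["nucleus", "golgi"])}
            for _ in range(120)
        ]
        pred = [
            t if rng.random() < 0.6 else {rng.choice(classes)} for t in truth
        ]
        rep = multiclass_report(truth, pred)
        pooled = (rep.single_acc * rep.n_single + rep.multi_acc * rep.n_multi) / rep.n_total
        assert rep.overall_acc == pytest.approx(pooled)

    def test_report_rows_layout(self):
        truth = ["nucleus"] * 3 + [{"cytoplasm", "nucleus"}] * 2
        pred = ["nucleus", "nucleus", "plastid", {"cytoplasm", "nucleus"}, {"golgi"}]
        rep = multiclass_report(truth, pred)
        rows = rep.rows.set_index("location")
        assert rows.loc["nucleus", "n"] == 3 and rows.loc["nucleus", "correct"] == 2
        assert rows.loc["cytoplasm+nucleus", "correct"] == 1
        assert rows.loc["Total all", "n"] == 5

    def test_label_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            multiclass_report([{"moon"}], [{"moon"}])


class TestAUC:
    def test_perfect_and_reversed(self):
        truth = [0, 0, 1, 1]
        assert roc_auc(truth, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert roc_auc(truth, [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_random_scores_near_half(self, rng):
        truth = rng.integers(0, 2, size=2000)
        scores = rng.random(2000)
        assert roc_auc(truth, scores) == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariant(self, rng):
        truth = rng.integers(0, 2, size=200)
        scores = rng.random(200)
        assert roc_auc(truth, scores) == pytest.approx(
            roc_auc(truth, np.exp(5 * scores)), abs=1e-12
        )

    def test_one_class_is_nan(self):
        assert np.isnan(roc_auc([1, 1, 1], [0.1, 0.2, 0.3]))

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        truth = rng.integers(0, 2, size=60)
        scores = rng.integers(0, 5, size=60).astype(float)  # heavy ties
        assert roc_auc(truth, scores) == pytest.approx(
            oracles.auc_pair_counting_oracle(truth, scores)
        )


class TestCrossValidate:
    def test_leave_one_out_toy_runs(self, tiny_data):
        dataset, _, features = tiny_data
        y = [r.labels for r in dataset]
        rep = cross_validate(features, y, folds=len(y), seed=0)
        assert rep.n_total == len(y)
        assert set(rep.base_accuracies) == {"knn", "rf", "xgb"}

    def test_same_seed_identical_metrics(self, tiny_data):
        dataset, _, features = tiny_data
        y = [r.labels for r in dataset]
        a = cross_validate(features, y, folds=4, seed=3)
        b = cross_validate(features, y, folds=4, seed=3)
        assert a.overall_acc == b.overall_acc
        assert a.fold_accuracies == b.fold_accuracies

    def test_too_few_folds_rejected(self, tiny_data):
        dataset, _, features = tiny_data
        y = [r.labels for r in dataset]
        with pytest.raises(ValueError):
            cross_validate(features, y, folds=1)

    def test_strong_signal_recovery(self, strong_cv):
        assert strong_cv.overall_acc >= 0.90
        assert strong_cv.overall_acc >= min(strong_cv.base_accuracies.values())

    def test_null_signal_sits_at_chance(self, null_cv):
        assert abs(null_cv.overall_acc - 1 / 11) <= 0.05


class TestPCC:
    def test_indicator_feature_is_one(self):
        y = ["nucleus"] * 5 + ["golgi"] * 5
        X = pd.DataFrame({"ind": [1.0] * 5 + [0.0] * 5, "neg": [0.0] * 5 + [1.0] * 5})
        top = pcc_feature_analysis(X, y, "nucleus", top_n=2).set_index("feature")
        assert top.loc["ind", "pcc"] == pytest.approx(1.0)
        assert top.loc["neg", "pcc"] == pytest.approx(-1.0)

    def test_noise_feature_uncorrelated(self, rng):
        y = ["nucleus"] * 2500 + ["golgi"] * 2500
        X = pd.DataFrame({"noise": rng.standard_normal(5000)})
        top = pcc_feature_analysis(X, y, "nucleus", top_n=1)
        assert abs(top["pcc"][0]) < 0.05

    def test_zero_variance_warns_and_scores_zero(self):
        y = ["nucleus"] * 4 + ["golgi"] * 4
        X = pd.DataFrame({"const": np.ones(8), "ind": [1.0] * 4 + [0.0] * 4})
        with pytest.warns(UserWarning):
            top = pcc_feature_analysis(X, y, "nucleus", top_n=2).set_index("feature")
        assert top.loc["const", "pcc"] == 0.0

    def test_absent_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            pcc_feature_analysis(X, ["nucleus", "nucleus"], "golgi")
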