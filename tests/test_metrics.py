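import itertools
import math

import numpy as np
import pytest

from navvar.metrics import (MetricError, ZeroR, binary_counts, entropy,
                            information_gain, macro_ovr_auc, mcc,
                            mcc_from_counts, mdl_discretize, roc_auc,
                            roc_curve)


def mcc_oracle(tp, fp, fn, tn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / denom


def auc_oracle(scores, labels, positive=True):
    """Brute-force concordant-pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def info_gain_oracle(feature, labels):
    """Direct entropy arithmetic for a categorical feature."""
    n = len(labels)
    base = entropy(labels)
    cond = 0.0
    for value in set(feature):
        group = [l for f, l in zip(feature, labels) if f == value]
        cond += len(group) / n * entropy(group)
    return base - cond


class TestMCC:
    def test_perfect_prediction(self):
        assert mcc(["a", "b", "a"], ["a", "b", "a"]) == pytest.approx(1.0)

    def test_constant_prediction_is_zero(self):
        assert mcc(["a", "b", "a"], ["a", "a", "a"]) == 0.0

    def test_worked_counts(self):
        # TP=45, TN=25, FP=10, FN=20 against the direct formula
        assert mcc_from_counts(45, 10, 20, 25) == pytest.approx(
            mcc_oracle(45, 10, 20, 25))

    def test_binary_agrees_with_formula_oracle_randomized(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 12))
            y_true = rng.integers(0, 2, size=n).tolist()
            y_pred = rng.integers(0, 2, size=n).tolist()
            counts = binary_counts(y_true, y_pred, positive=1)
            assert mcc(y_true, y_pred) == pytest.approx(
                mcc_oracle(counts["tp"], counts["fp"],
                           counts["fn"], counts["tn"]), abs=1e-12)

    def test_multiclass_reduces_to_binary(self, rng):
        y_true = rng.integers(0, 2, size=30).tolist()
        y_pred = rng.integers(0, 2, size=30).tolist()
        counts = binary_counts(y_true, y_pred, positive=1)
        assert mcc(y_true, y_pred) == pytest.approx(mcc_oracle(
            counts["tp"], counts["fp"], counts["fn"], counts["tn"]))

    def test_three_class_perfect_and_degenerate(self):
        y = ["a", "b", "c", "a"]
        assert mcc(y, y) == pytest.approx(1.0)
        assert mcc(y, ["a"] * 4) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(MetricError):
            mcc_from_counts(-1, 0, 0, 1)


class TestAUC:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_constant_scores_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 0, 0, 1, 0]) == 0.5

    def test_hand_case_three_points(self):
        # positives 0.9 and 0.5, negative 0.5: one concordant pair plus one
        # tie at half credit = 1.5 of 2
        assert roc_auc([0.9, 0.5, 0.5], [1, 1, 0]) == pytest.approx(0.75)
        # without the tie the discordant pair earns nothing
        assert roc_auc([0.9, 0.4, 0.5], [1, 1, 0]) == pytest.approx(0.5)

    def test_agrees_with_pair_counting_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 12))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            assert roc_auc(scores, labels, positive=1) == pytest.approx(
                auc_oracle(scores, labels, positive=1), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels, positive=1)
        b = roc_auc(np.exp(3 * scores) + 7, labels, positive=1)
        assert a == pytest.approx(b)

    def test_single_class_flagged(self):
        with pytest.raises(MetricError):
            roc_auc([0.1, 0.2], [1, 1], positive=1)

    def test_curve_endpoints(self):
        curve = roc_curve([0.9, 0.1, 0.5], [1, 0, 1], positive=1)
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)

    def test_macro_ovr_matches_mean_of_binary(self, rng):
        classes = ["neg", "mid", "pos"]
        y = rng.choice(classes, size=30).tolist()
        y[:3] = classes
        scores = rng.random((30, 3))
        expected = np.mean([
            auc_oracle(scores[:, j], [t == c for t in y])
            for j, c in enumerate(classes)])
        assert macro_ovr_auc(scores, y, classes) == pytest.approx(expected)


class TestInformationGain:
    def test_four_row_worked_case(self):
        assert information_gain(["a", "a", "b", "b"],
                                ["+", "+", "-", "-"]) == pytest.approx(1.0)

    def test_feature_equal_to_balanced_labels_is_one_bit(self):
        labels = [0, 1] * 8
        assert information_gain(labels, labels, numeric=False) == pytest.approx(1.0)

    def test_constant_feature_zero(self):
        assert information_gain(["x"] * 10, [0, 1] * 5) == 0.0

    def test_constant_labels_zero(self):
        assert information_gain(["a", "b"] * 5, [1] * 10) == 0.0

    def test_relabeling_invariance(self, rng):
        feature = rng.choice(list("abc"), size=40).tolist()
        labels = rng.integers(0, 2, size=40).tolist()
        renamed = [{"a": "z", "b": "q", "c": "m"}[f] for f in feature]
        assert information_gain(feature, labels) == pytest.approx(
            information_gain(renamed, labels))

    def test_agrees_with_entropy_oracle_randomized(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 12))
            feature = rng.choice(list("abc"), size=n).tolist()
            labels = rng.integers(0, 2, size=n).tolist()
            assert information_gain(feature, labels) == pytest.approx(
                max(info_gain_oracle(feature, labels), 0.0), abs=1e-12)

    def test_mdl_finds_clean_threshold(self):
        values = list(range(20))
        labels = [0] * 10 + [1] * 10
        cuts = mdl_discretize(values, labels)
        assert cuts == [9.5]
        assert information_gain(values, labels) == pytest.approx(1.0)

    def test_mdl_rejects_noise_split(self, rng):
        values = rng.normal(size=40).tolist()
        labels = rng.integers(0, 2, size=40).tolist()
        # independent numeric feature: MDL keeps a single bin, gain 0
        assert information_gain(values, labels) == 0.0 or \
            information_gain(values, labels) < 0.35


class TestZeroR:
    def test_predicts_majority_and_matching_accuracy(self):
        labels = ["affected"] * 90 + ["unaffected"] * 10
        clf = ZeroR().fit(None, labels)
        assert clf.majority_ == "affected"
        assert clf.accuracy(labels) == pytest.approx(0.90)

    def test_tie_breaks_lexicographically(self):
        clf = ZeroR().fit(None, ["b", "a"])
        assert clf.majority_ == "a"

    def test_mcc_zero_on_any_test_set(self, rng):
        clf = ZeroR().fit(None, ["x"] * 6 + ["y"] * 4)
        y_test = rng.choice(["x", "y"], size=30).tolist()
        assert mcc(y_test, clf.predict(range(30)).tolist()) == 0.0

    def test_constant_scores_give_half_auc(self):
        clf = ZeroR().fit(None, [1, 1, 0])
        scores = clf.predict_proba(range(4))[:, 1]
        assert roc_auc(scores, [1, 0, 1, 0], positive=1) == 0.5

    def test_empty_training_rejected(self):
        with pytest.raises(MetricError):
            ZeroR().fit(None, [])
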