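import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgdyn import (ConfusionCounts, auc_score, binary_metrics,
                    confusion_from_predictions, multiclass_metrics)


class TestConfusion:
    def test_basic_counts(self):
        c = confusion_from_predictions([1, 1, 0, 0], [1, 0, 0, 0], positive=1)
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 2, 0)

    def test_perfect_predictions(self):
        c = confusion_from_predictions(["a", "b"], ["a", "b"], positive="a")
        assert c.FP == 0 and c.FN == 0

    def test_positive_class_swap_exchanges_counts(self):
        y, p = [1, 1, 0, 0, 0], [1, 0, 1, 0, 0]
        a = confusion_from_predictions(y, p, positive=1)
        b = confusion_from_predictions(y, p, positive=0)
        assert (a.TP, a.TN, a.FP, a.FN) == (b.TN, b.TP, b.FN, b.FP)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_from_predictions([1], [1, 0], positive=1)


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        rep = binary_metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert rep.accuracy == 100.0 and rep.precision == 100.0
        assert rep.recall == 100.0 and rep.f1 == 100.0
        assert rep.kappa == 1.0 and rep.mcc == 1.0
        assert rep.csi == 1.0 and rep.gmean == 1.0

    def test_worked_confusion_matrix(self):
        # hand-derived: TP=3, FP=1, FN=2, TN=4
        rep = binary_metrics(ConfusionCounts(TP=3, TN=4, FP=1, FN=2))
        assert rep.accuracy == pytest.approx(70.0)
        assert rep.precision == pytest.approx(75.0)
        assert rep.recall == pytest.approx(60.0)
        assert rep.f1 == pytest.approx(66.6667, abs=1e-3)
        assert rep.kappa == pytest.approx(0.4)
        assert rep.mcc == pytest.approx(0.40825, abs=1e-4)
        assert rep.csi == pytest.approx(0.5)
        assert rep.gmean == pytest.approx(0.69282, abs=1e-4)

    def test_as_printed_specificity_variant(self):
        rep = binary_metrics(ConfusionCounts(TP=3, TN=4, FP=1, FN=2),
                             specificity_mode="as_printed")
        # specificity becomes TN/(FN+TN) = 4/6
        assert rep.gmean == pytest.approx(np.sqrt(0.6 * 4.0 / 6.0))
        assert rep.specificity_mode == "as_printed"

    def test_zero_denominator_sentinels(self):
        rep = binary_metrics(ConfusionCounts(TP=0, TN=3, FP=0, FN=2))
        assert rep.precision is None      # no positive predictions
        assert rep.recall == 0.0          # FN > 0

    def test_kappa_equals_classical_cohen(self, rng):
        # Eq-style kappa vs (po - pe) / (1 - pe) on 10^4 random tables
        counts = rng.integers(0, 50, size=(10_000, 4))
        for tp, tn, fp, fn in counts:
            n = tp + tn + fp + fn
            if n == 0:
                continue
            rep = binary_metrics(ConfusionCounts(int(tp), int(tn),
                                                 int(fp), int(fn)))
            po = (tp + tn) / n
            pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n ** 2
            if pe == 1.0:
                assert rep.kappa is None or rep.kappa == 0.0
            else:
                classical = (po - pe) / (1.0 - pe)
                assert rep.kappa == pytest.approx(classical, abs=1e-12)

    def test_kappa_matches_sklearn_spot_check(self, rng):
        from sklearn.metrics import cohen_kappa_score
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 20, size=4)
            y = [1] * (tp + fn) + [0] * (tn + fp)
            p = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            rep = binary_metrics(ConfusionCounts(int(tp), int(tn),
                                                 int(fp), int(fn)))
            assert rep.kappa == pytest.approx(cohen_kappa_score(y, p))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 30), tn=st.integers(0, 30),
           fp=st.integers(0, 30), fn=st.integers(0, 30))
    def test_mcc_invariant_under_class_swap(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        a = binary_metrics(ConfusionCounts(tp, tn, fp, fn)).mcc
        b = binary_metrics(ConfusionCounts(tn, tp, fn, fp)).mcc
        assert (a is None and b is None) or a == pytest.approx(b, abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_score([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_three_of_four_concordant_pairs(self):
        assert auc_score([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.1]) == 0.75

    def test_all_ties_give_half(self):
        assert auc_score([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([1, 1, 1], [0.1, 0.2, 0.3])

    def test_rank_auc_equals_trapezoidal(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(1000):
            n = rng.integers(4, 30)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = rng.normal(size=n)
            assert auc_score(y, s) == pytest.approx(roc_auc_score(y, s),
                                                    abs=1e-12)

    def test_label_independent_scores_near_half(self, rng):
        y = np.array([1] * 2000 + [0] * 2000)
        s = rng.uniform(size=4000)
        assert 0.47 <= auc_score(y, s) <= 0.53


class TestMulticlass:
    def test_perfect_predictions_hit_maxima(self):
        y = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        rep = multiclass_metrics(y, y)
        assert rep.accuracy == 100.0 and rep.precision == 100.0
        assert rep.kappa == 1.0 and rep.mcc == 1.0
        assert rep.csi == 1.0 and rep.gmean == 1.0

    def test_one_class_collapse_on_balanced_three(self):
        y = ["a", "b", "c"] * 4
        p = ["a"] * 12
        rep = multiclass_metrics(y, p)
        assert rep.accuracy == pytest.approx(100.0 / 3.0)

    def test_weighted_recall_from_printed_confusion(self):
        # confusion [[2,1,0],[0,3,0],[1,0,3]] -> weighted recall 0.80
        y = ["a"] * 3 + ["b"] * 3 + ["c"] * 4
        p = ["a", "a", "b", "b", "b", "b", "c", "c", "c", "a"]
        rep = multiclass_metrics(y, p)
        assert rep.recall == pytest.approx(80.0)
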