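import numpy as np
import pytest

from ecgdyn import (GroupLabel, check_parametric_assumptions,
                    enumerate_comparisons, mann_whitney,
                    run_individual_stage, xroc_classify)
from ecgdyn.matrix import FeatureMatrix
from tests.conftest import make_gaussian_matrix


class TestComparisons:
    def test_eight_groups_give_28_pairs(self):
        comps = enumerate_comparisons(list(GroupLabel))
        assert len(comps) == 28
        assert len({c.label for c in comps}) == 28

    @pytest.mark.parametrize("k,expected", [(2, 1), (4, 6), (5, 10)])
    def test_pair_count_is_choose_2(self, k, expected):
        comps = enumerate_comparisons(list(GroupLabel)[:k])
        assert len(comps) == expected

    def test_first_named_group_is_positive(self):
        comps = enumerate_comparisons([GroupLabel.VHD, GroupLabel.MI])
        assert comps[0].label == "VHDvs.MI"
        assert comps[0].group_a == GroupLabel.VHD

    def test_duplicate_groups_rejected(self):
        with pytest.raises(ValueError):
            enumerate_comparisons([GroupLabel.HC, GroupLabel.HC])


class TestAssumptionChecks:
    def test_gaussian_equal_variance(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            normal, homo = check_parametric_assumptions(
                r.normal(size=200), r.normal(size=200))
            hits += normal and homo
        assert hits >= 9

    def test_exponential_fails_normality(self):
        r = np.random.default_rng(0)
        normal, _ = check_parametric_assumptions(
            r.exponential(size=500), r.normal(size=500))
        assert not normal

    def test_unequal_variances_fail_levene(self):
        r = np.random.default_rng(0)
        _, homo = check_parametric_assumptions(
            r.normal(scale=1.0, size=200), r.normal(scale=5.0, size=200))
        assert not homo

    def test_tiny_samples_indeterminate(self):
        assert check_parametric_assumptions([1.0, 2.0], [1.0, 2.0, 3.0]) == \
            (False, False)


class TestMannWhitney:
    def test_exact_p_for_complete_separation(self):
        # 5 vs 5 fully separated: two-sided exact p = 2/252
        p = mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2.0 / 252.0)

    def test_identical_samples_uninformative(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert mann_whitney(x, x) >= 0.99

    def test_symmetry(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=9)
        assert mann_whitney(a, b) == mann_whitney(b, a)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestXROC:
    def test_perfect_separation(self):
        for rule in ("nearest_mean", "roc_threshold"):
            acc, rec = xroc_classify([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], rule)
            assert acc == 100.0 and rec == 100.0

    def test_swamped_minority_recall_zero(self):
        # a single positive near the edge of a tight majority cluster:
        # its own fold has no positive training examples left, so
        # recall is 0 while overall accuracy stays high
        a = [0.35]
        b = list(np.linspace(0.0, 0.19, 20))
        acc, rec = xroc_classify(a, b, "nearest_mean")
        assert rec == 0.0
        assert acc >= 90.0

    def test_matches_manual_loocv_on_toy(self):
        # a = [0, 1, 2], b = [10, 11, 12]; every fold keeps the means
        # far apart so each held-out point is classified correctly
        acc, rec = xroc_classify([0.0, 1.0, 2.0], [10.0, 11.0, 12.0])
        assert (acc, rec) == (100.0, 100.0)
        # overlapping toy, worked by hand:
        # a=[0,4], b=[3,5,6]: hold 0 -> |0-4|=4 vs |0-14/3|; predicts a.
        # hold 4 -> means a:0, b:14/3; |4-0|=4 > |4-4.67|=0.67 -> b (miss).
        # hold 3 -> a mean 2, b mean 5.5; |3-2|=1 < 2.5 -> a (miss).
        # hold 5 -> b mean 4.5 vs a mean 2: b (hit). hold 6 -> b (hit).
        acc, rec = xroc_classify([0.0, 4.0], [3.0, 5.0, 6.0])
        assert acc == pytest.approx(60.0)
        assert rec == pytest.approx(50.0)

    def test_affine_invariance_of_nearest_mean(self, rng):
        a, b = rng.normal(size=8), rng.normal(loc=0.5, size=11)
        base = xroc_classify(a, b)
        assert xroc_classify(3.0 * a + 7.0, 3.0 * b + 7.0) == base

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            xroc_classify([1.0], [2.0])


class TestIndividualStage:
    def test_single_lead_yields_240_results_per_comparison(self):
        mat = make_gaussian_matrix(6, 6, seed=0)
        results, best, counts = run_individual_stage(mat)
        assert len(results) == 240
        # canonical naming order puts the rarer reference class first
        assert set(results["comparison"]) == {"MIvs.HC"}
        assert len(best) == 1

    def test_separable_groups_found(self):
        mat = make_gaussian_matrix(8, 8, seed=1, shift=4.0)
        _, best, _ = run_individual_stage(mat)
        assert best.iloc[0]["accuracy"] >= 90.0

    def test_counts_table_layout(self):
        mat = make_gaussian_matrix(8, 8, seed=2, shift=4.0)
        results, _, counts = run_individual_stage(mat)
        assert list(counts.columns[1:]) == [
            "ApEn", "CorrDim", "DFA", "En", "H", "EH", "K", "LogEn",
            "ELay", "ShaEn", "Total"]
        assert counts.iloc[-1]["comparison"] == "Total"
        assert counts.iloc[0]["Total"] == int(results["significant"].sum())

    def test_absent_group_skipped_with_warning(self):
        mat = make_gaussian_matrix(5, 5, seed=3)
        comps = enumerate_comparisons([GroupLabel.HC, GroupLabel.MI,
                                       GroupLabel.BBB])
        with pytest.warns(UserWarning, match="skipped"):
            results, _, _ = run_individual_stage(mat, comps)
        assert set(results["comparison"]) == {"HCvs.MI"}

    def test_bh_correction_is_more_conservative(self):
        mat = make_gaussian_matrix(10, 10, seed=4, shift=0.8)
        raw, _, _ = run_individual_stage(mat, mtc="none")
        adj, _, _ = run_individual_stage(mat, mtc="bh")
        assert adj["significant"].sum() <= raw["significant"].sum()
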