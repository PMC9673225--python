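"""Diagnostic-accuracy statistics: AUROC, DeLong, operating points, cohort tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from icpw import diagnostics as dg
from icpw.errors import InvalidParameterError


def brute_force_auc(scores, labels):
    """Pairwise concordance by explicit enumeration (test oracle)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        assert dg.empirical_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0

    def test_pure_ties(self):
        assert dg.empirical_auc([5, 5, 5, 5], [0, 0, 1, 1]).auc == 0.5

    def test_mixed_ties_brute_force_value(self):
        assert dg.empirical_auc([1, 2, 2, 3], [0, 0, 1, 1]).auc == pytest.approx(0.875)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidParameterError):
            dg.empirical_auc([1, 2, 3], [1, 1, 1])

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, data):
        n = data.draw(st.integers(4, 30))
        scores = data.draw(
            st.lists(st.integers(0, 8), min_size=n, max_size=n).map(
                lambda xs: [x / 2 for x in xs]  # plenty of ties
            )
        )
        n_pos = data.draw(st.integers(1, n - 1))
        labels = [1] * n_pos + [0] * (n - n_pos)
        auc = dg.empirical_auc(scores, labels).auc
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_complement_identity(self, data):
        n = data.draw(st.integers(4, 25))
        scores = np.array(data.draw(st.lists(st.integers(-5, 5), min_size=n, max_size=n)), dtype=float)
        n_pos = data.draw(st.integers(1, n - 1))
        labels = np.array([1] * n_pos + [0] * (n - n_pos))
        a = dg.empirical_auc(scores, labels).auc
        b = dg.empirical_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestDelongCi:
    def test_perfect_separation_degenerate(self):
        res = dg.delong_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0 and res.degenerate
        assert res.ci_low == res.ci_high == 1.0

    def test_se_agrees_with_stratified_bootstrap(self):
        rng = np.random.default_rng(15)
        pos = rng.normal(1.0, 1.0, 50)
        neg = rng.normal(0.0, 1.0, 60)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 50 + [0] * 60)
        res = dg.delong_ci(scores, labels)
        boots = []
        for _ in range(2000):
            bp = rng.choice(pos, 50, replace=True)
            bn = rng.choice(neg, 60, replace=True)
            boots.append(
                dg.empirical_auc(
                    np.concatenate([bp, bn]), labels
                ).auc
            )
        boot_se = np.std(boots, ddof=1)
        assert res.se == pytest.approx(boot_se, rel=0.15)

    def test_null_coverage_of_95_ci(self):
        rng = np.random.default_rng(99)
        covered = 0
        for _ in range(200):
            scores = rng.normal(0, 1, 40)
            labels = np.array([1] * 15 + [0] * 25)
            rng.shuffle(labels)
            res = dg.delong_ci(scores, labels)
            covered += res.ci_low <= 0.5 <= res.ci_high
        assert covered >= 0.93 * 200

    def test_requires_two_per_class(self):
        with pytest.raises(InvalidParameterError):
            dg.delong_ci([1, 2, 3], [1, 0, 0])


class TestDelongCompare:
    def test_identical_classifiers(self):
        scores = [0.2, 0.8, 0.4, 0.9, 0.1, 0.7]
        labels = [0, 1, 0, 1, 0, 1]
        z, p = dg.delong_compare(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_matches_hand_evaluated_placement_covariance(self):
        # 3 positives, 3 negatives; classifier a separates, b anti-separates
        labels = np.array([1, 1, 1, 0, 0, 0])
        a = np.array([10.0, 11.0, 12.0, 1.0, 2.0, 3.0])
        b = -a
        z, p = dg.delong_compare(a, b, labels)
        # brute-force placement values computed by definition
        pos_idx, neg_idx = np.where(labels == 1)[0], np.where(labels == 0)[0]

        def placements(s):
            v10 = [np.mean([(s[i] > s[j]) + 0.5 * (s[i] == s[j]) for j in neg_idx])
                   for i in pos_idx]
            v01 = [np.mean([(s[i] > s[j]) + 0.5 * (s[i] == s[j]) for i in pos_idx])
                   for j in neg_idx]
            return np.array(v10), np.array(v01)

        v10a, v01a = placements(a)
        v10b, v01b = placements(b)
        auc_a, auc_b = v10a.mean(), v10b.mean()
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / 3 + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / 3
        if var > 0:
            assert z == pytest.approx((auc_a - auc_b) / np.sqrt(var))
        else:
            assert (z, p) == (0.0, 1.0)

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            labels = np.array([1] * 30 + [0] * 70)
            a = rng.normal(0, 1, 100)
            b = rng.normal(0, 1, 100)
            _, p = dg.delong_compare(a, b, labels)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(InvalidParameterError):
            dg.delong_compare([1, 2], [1, 2, 3], [0, 1, 1])


class TestConfusionAtCutoff:
    def test_clean_separation(self):
        perf = dg.confusion_at_cutoff([1.0, 1.1, 1.3, 1.5], [0, 0, 1, 1], 1.2)
        assert perf.sensitivity == 1.0 and perf.specificity == 1.0

    def test_eleven_of_thirteen_positives(self):
        scores = np.concatenate([np.full(11, 1.5), np.full(2, 1.0), np.full(59, 1.0)])
        labels = np.array([1] * 13 + [0] * 59)
        perf = dg.confusion_at_cutoff(scores, labels, 1.2)
        assert perf.sensitivity == pytest.approx(11 / 13)
        assert round(100 * perf.sensitivity) == 85

    def test_cutoff_above_max(self):
        perf = dg.confusion_at_cutoff([1.0, 2.0], [0, 1], 5.0)
        assert perf.sensitivity == 0.0 and perf.specificity == 1.0

    def test_boundary_score_counts_negative(self):
        perf = dg.confusion_at_cutoff([1.2, 1.2], [1, 0], 1.2)
        assert perf.sensitivity == 0.0 and perf.specificity == 1.0

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_counts_partition_and_wilson_cis_bounded(self, data):
        n = data.draw(st.integers(4, 40))
        scores = np.array(data.draw(st.lists(st.floats(0, 3, allow_nan=False),
                                             min_size=n, max_size=n)))
        n_pos = data.draw(st.integers(1, n - 1))
        labels = np.array([1] * n_pos + [0] * (n - n_pos))
        cutoff = data.draw(st.floats(0, 3))
        perf = dg.confusion_at_cutoff(scores, labels, cutoff)
        assert perf.tp + perf.fp + perf.tn + perf.fn == n
        for lo, hi in (perf.sens_ci, perf.spec_ci):
            assert 0 <= lo <= hi <= 1


class TestYouden:
    def test_perfect_separation(self):
        cutoff, j = dg.youden_optimal([1, 2, 10, 11], [0, 0, 1, 1])
        assert j == pytest.approx(1.0)
        assert 2 < cutoff < 10

    def test_two_point_midpoint(self):
        cutoff, _ = dg.youden_optimal([1.0, 2.0], [0, 1])
        assert cutoff == pytest.approx(1.5)

    def test_random_labels_give_small_j(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, 400)
        labels = rng.integers(0, 2, 400)
        while labels.sum() in (0, 400):  # pragma: no cover
            labels = rng.integers(0, 2, 400)
        _, j = dg.youden_optimal(scores, labels)
        assert j < 0.3


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        r, p = dg.pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_exact_anti_linear(self):
        x = np.arange(10.0)
        r, _ = dg.pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(InvalidParameterError):
            dg.pearson_r([1, 1, 1], [1, 2, 3])


class TestCategorical:
    def test_iht_by_outcome_table_chi_square(self):
        res = dg.group_compare_categorical([[3, 12], [5, 42], [5, 5]], force="chi2")
        assert res.statistic == pytest.approx(8.683, abs=0.001)
        assert res.pvalue == pytest.approx(0.013, abs=5e-4)

    def test_homogeneous_table(self):
        res = dg.group_compare_categorical([[10, 10], [10, 10]])
        assert res.pvalue == pytest.approx(1.0)
        assert res.test_used == "chi-square"

    def test_small_expected_counts_dispatch_to_fisher(self):
        res = dg.group_compare_categorical([[3, 12], [5, 42], [5, 5]])
        assert res.test_used == "fisher"
        # frozen from R: fisher.test(matrix(c(3,5,5,12,42,5),3,2))
        assert res.pvalue == pytest.approx(0.01524404, abs=1e-6)

    def test_fisher_2x2_matches_r(self):
        res = dg.group_compare_categorical([[3, 9], [5, 2]])
        assert res.test_used == "fisher"
        # frozen from R: fisher.test(matrix(c(3,5,9,2),2,2))
        assert res.pvalue == pytest.approx(0.07394618, abs=1e-6)

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidParameterError):
            dg.group_compare_categorical([[0, 0], [5, 5]])


class TestContinuous:
    def test_identical_groups_pure_ties(self):
        res = dg.group_compare_continuous([[3, 3, 3], [3, 3, 3], [3, 3, 3]])
        assert res.pvalue == pytest.approx(1.0)
        assert res.test_used == "kruskal-wallis"

    def test_shifted_group_flagged_by_posthoc_only(self):
        rng = np.random.default_rng(21)
        groups = [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(2, 1, 50)]
        res = dg.group_compare_continuous(groups)
        assert res.pvalue < 1e-3
        flagged = {frozenset((i, j)) for i, j, p in res.posthoc if p < 0.05}
        assert flagged == {frozenset((0, 2)), frozenset((1, 2))}

    def test_two_groups_consistent_with_t_test(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
        res = dg.group_compare_continuous([a, b], family="anova")
        t = stats.ttest_ind(a, b)
        assert res.pvalue == pytest.approx(t.pvalue, abs=1e-12)
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-9)

    def test_skewed_data_dispatch_to_kruskal(self):
        rng = np.random.default_rng(6)
        groups = [rng.lognormal(0, 1.2, 40) for _ in range(3)]
        res = dg.group_compare_continuous(groups)
        assert res.test_used == "kruskal-wallis"

    def test_tiny_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            dg.group_compare_continuous([[1, 2, 3], [4]])


class TestAucSampleSize:
    def test_tiny_power_gives_minimal_design(self):
        total, n_pos, n_neg = dg.auc_sample_size(0.85, 0.6, power=1e-6)
        assert (total, n_pos, n_neg) == (4, 2, 2)

    def test_ratio_monotonicity(self):
        t1, _, _ = dg.auc_sample_size(0.85, 0.6, 0.8, 0.05, 1.0)
        t2, _, _ = dg.auc_sample_size(0.85, 0.6, 0.8, 0.05, 2.0)
        assert t2 >= t1

    def test_infeasible_rejected(self):
        with pytest.raises(InvalidParameterError):
            dg.auc_sample_size(0.6, 0.85)

    def test_harder_alternative_needs_more_patients(self):
        easy, _, _ = dg.auc_sample_size(0.85, 0.6)
        hard, _, _ = dg.auc_sample_size(0.7, 0.6)
        assert hard > easy
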