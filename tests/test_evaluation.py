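"""The rank-statistics toolkit: correlation, ROC/AUC, and two-group tests,
cross-checked against independent oracles (brute force, scipy, sklearn)."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import isens
from isens import PairedSamples


def paired(x, y):
    return PairedSamples(np.asarray(x, float), np.asarray(y, float))


class TestPearson:
    def test_perfect_linear(self):
        assert isens.pearson(paired([1, 2, 3], [2, 4, 6])).coefficient == 1.0
        assert isens.pearson(paired([1, 2, 3], [1, 2, 3])).coefficient == 1.0

    def test_hand_computed_value(self):
        r = isens.pearson(paired([1, 2, 3], [1, 4, 9])).coefficient
        assert r == pytest.approx(0.989743318610787, rel=1e-12)

    def test_matches_scipy_on_random_data(self, rng):
        x = rng.normal(size=200)
        y = 0.4 * x + rng.normal(size=200)
        ours = isens.pearson(paired(x, y)).coefficient
        ref = scipy.stats.pearsonr(x, y).statistic
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_constant_series_undefined(self):
        with pytest.raises(isens.UndefinedStatisticError):
            isens.pearson(paired([1, 1, 1], [1, 2, 3]))

    def test_too_short_undefined(self):
        with pytest.raises(isens.UndefinedStatisticError):
            isens.pearson(paired([1, 2], [3, 4]))


class TestSpearman:
    def test_monotone_nonlinear_is_exactly_one(self):
        assert isens.spearman(paired([1, 2, 3], [1, 4, 9])).coefficient == 1.0
        assert isens.spearman(paired([1, 2, 3], [9, 4, 1])).coefficient == -1.0

    def test_rank_preservation_under_increasing_transform(self, rng):
        x = rng.normal(size=100)
        assert isens.spearman(paired(x, np.exp(x))).coefficient == 1.0

    def test_log_invariance_exact(self, rng):
        """Spearman is unchanged by log-transforming a positive series."""
        x = rng.normal(size=150)
        y = rng.lognormal(1.0, 0.5, size=150)
        a = isens.spearman(paired(x, y)).coefficient
        b = isens.spearman(paired(x, np.log(y))).coefficient
        assert a == b

    def test_equals_pearson_of_ranks_and_scipy(self, rng):
        x = rng.normal(size=80)
        y = rng.normal(size=80)
        ours = isens.spearman(paired(x, y)).coefficient
        via_ranks = isens.pearson(
            paired(isens.midranks(x), isens.midranks(y))
        ).coefficient
        ref = scipy.stats.spearmanr(x, y).statistic
        assert ours == via_ranks
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_midranks_average_ties(self):
        assert np.array_equal(
            isens.midranks([10.0, 20.0, 20.0, 30.0]), [1.0, 2.5, 2.5, 4.0]
        )
        ref = scipy.stats.rankdata([3, 1, 4, 1, 5, 9, 2, 6, 5, 3])
        assert np.array_equal(
            isens.midranks([3, 1, 4, 1, 5, 9, 2, 6, 5, 3]), ref
        )


class TestSpearmanToPearson:
    @pytest.mark.parametrize("rho,expected", [(0.0, 0.0), (1.0, 1.0), (-1.0, -1.0)])
    def test_endpoints_exact(self, rho, expected):
        assert isens.spearman_to_pearson(rho) == expected

    def test_hand_computed_value(self):
        assert isens.spearman_to_pearson(0.5) == pytest.approx(
            0.5176380902050415, rel=1e-12
        )

    @given(st.floats(-1.0, 1.0))
    def test_odd_and_bounded(self, rho):
        r = isens.spearman_to_pearson(rho)
        assert -1.0 <= r <= 1.0
        assert isens.spearman_to_pearson(-rho) == -r

    def test_strictly_increasing(self):
        grid = np.linspace(-1, 1, 201)
        out = [isens.spearman_to_pearson(v) for v in grid]
        assert all(b > a for a, b in zip(out, out[1:]))

    def test_domain_error(self):
        with pytest.raises(isens.InvalidInputError):
            isens.spearman_to_pearson(1.5)


class TestROC:
    def test_perfect_separation(self):
        curve = isens.roc_curve(
            [5.0, 6.0, 1.0, 2.0], [True, True, False, False]
        )
        assert curve.auc == 1.0
        assert any(np.array_equal(p, [0.0, 1.0]) for p in curve.points)

    def test_interleaved_example(self):
        curve = isens.roc_curve(
            [1.0, 2.0, 3.0, 4.0], [True, False, True, False]
        )
        assert curve.auc == pytest.approx(0.25, abs=1e-15)

    def test_curve_shape_invariants(self, rng):
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.4
        curve = isens.roc_curve(scores, labels)
        assert np.array_equal(curve.points[0], [0.0, 0.0])
        assert np.array_equal(curve.points[-1], [1.0, 1.0])
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    @pytest.mark.parametrize("n,with_ties", [(20, False), (200, True), (500, True)])
    def test_auc_equals_probability_oracle(self, rng, n, with_ties):
        scores = rng.normal(size=n)
        if with_ties:
            scores = np.round(scores, 1)  # force tied scores
        labels = rng.random(n) < 0.35
        curve = isens.roc_curve(scores, labels)
        oracle = isens.auc_probability_oracle(scores[labels], scores[~labels])
        assert curve.auc == pytest.approx(oracle, abs=1e-12)
        assert curve.auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_monotone_transform_leaves_points_identical(self, rng):
        """The basis of the index equivalence: any strictly increasing
        re-expression of the scores produces the identical ROC point set."""
        scores = rng.lognormal(0.5, 0.4, size=80)
        labels = rng.random(80) < 0.3
        base = isens.roc_curve(scores, labels)
        for transformed in (np.log(scores), 3.0 * scores + 7.0):
            other = isens.roc_curve(transformed, labels)
            assert np.array_equal(base.points, other.points)
            assert base.auc == other.auc

    def test_orientation_reversal_matches_inverse_index(self, fast_cohort):
        """HOMA-IR (resistance-up) and QUICKI (sensitivity-up, reversed)
        give bitwise-identical ROC curves against the clamp label."""
        a = isens.roc_curve(
            fast_cohort.homa_ir, fast_cohort.resistant, "higher_is_positive"
        )
        b = isens.roc_curve(
            fast_cohort.quicki, fast_cohort.resistant, "lower_is_positive"
        )
        assert np.array_equal(a.points, b.points)
        assert a.auc == b.auc

    def test_single_class_rejected(self):
        with pytest.raises(isens.DegenerateLabelsError):
            isens.roc_curve([1.0, 2.0, 3.0], [True, True, True])
        with pytest.raises(isens.DegenerateLabelsError):
            isens.auc_probability_oracle([], [1.0])

    def test_oracle_tiny_cases(self):
        assert isens.auc_probability_oracle([2.0], [1.0]) == 1.0
        assert isens.auc_probability_oracle([1.0], [1.0]) == 0.5


class TestClassifyResistant:
    def test_strict_cutoff(self):
        assert isens.classify_resistant(4.7, 4.7) is False
        assert isens.classify_resistant(4.69, 4.7) is True
        assert isens.classify_resistant(100.0, 4.7) is False

    def test_positive_inputs_required(self):
        with pytest.raises(isens.InvalidInputError):
            isens.classify_resistant(-1.0, 4.7)


def _exact_u_statistic(a, b):
    """Brute-force U for group a: wins + half-ties over all (a, b) pairs."""
    return sum(
        1.0 if x > y else 0.5 if x == y else 0.0
        for x, y in itertools.product(a, b)
    )


class TestGroupTests:
    def test_identical_groups_are_null(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        mw, tt = isens.group_tests(vals, vals)
        assert mw.p_value == pytest.approx(1.0, abs=1e-12)
        assert tt.statistic == 0.0

    def test_u_statistic_matches_pair_counting(self, rng):
        for _ in range(25):
            a = np.round(rng.normal(size=rng.integers(3, 10)), 1)
            b = np.round(rng.normal(size=rng.integers(3, 10)), 1)
            mw = isens.mann_whitney(a, b)
            assert mw.statistic == pytest.approx(
                _exact_u_statistic(a, b), abs=1e-12
            )

    def test_matches_scipy_asymptotic(self, rng):
        a = rng.normal(0.3, 1.0, size=40)
        b = rng.normal(0.0, 1.0, size=55)
        mw = isens.mann_whitney(a, b)
        ref = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        )
        assert mw.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert mw.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_welch_matches_scipy(self, rng):
        a = rng.normal(0.5, 1.4, size=30)
        b = rng.normal(0.0, 0.7, size=45)
        tt = isens.welch_t_test(a, b)
        ref = scipy.stats.ttest_ind(a, b, equal_var=False)
        assert tt.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert tt.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_mann_whitney_identical_across_indices(self, fast_cohort):
        """Rank tests give the same answer through HOMA-IR, FIRI, and
        orientation-reversed QUICKI; Welch t-tests do not."""
        m = fast_cohort.m_lbm
        split = m < np.median(m)
        results = {}
        for name, scores in (
            ("homa", fast_cohort.homa_ir),
            ("firi", fast_cohort.firi),
            ("quicki_rev", -fast_cohort.quicki),
        ):
            results[name] = isens.mann_whitney(scores[split], scores[~split])
        u = {r.statistic for r in results.values()}
        p = {r.p_value for r in results.values()}
        assert len(u) == 1 and len(p) == 1
        # two-sided p is orientation-invariant even without reversal
        raw_q = isens.mann_whitney(
            fast_cohort.quicki[split], fast_cohort.quicki[~split]
        )
        assert raw_q.p_value == results["homa"].p_value
        t_homa = isens.welch_t_test(
            fast_cohort.homa_ir[split], fast_cohort.homa_ir[~split]
        )
        t_quicki = isens.welch_t_test(
            fast_cohort.quicki[split], fast_cohort.quicki[~split]
        )
        assert t_homa.p_value != t_quicki.p_value

    def test_welch_t_invariant_under_common_scaling(self, fast_cohort):
        """HOMA-IR and FIRI differ by the factor 25/22.5, which cancels in
        the t statistic."""
        m = fast_cohort.m_lbm
        split = m < np.median(m)
        t_h = isens.welch_t_test(
            fast_cohort.homa_ir[split], fast_cohort.homa_ir[~split]
        )
        t_f = isens.welch_t_test(
            fast_cohort.firi[split], fast_cohort.firi[~split]
        )
        assert t_h.statistic == pytest.approx(t_f.statistic, rel=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(isens.DegenerateDataError):
            isens.welch_t_test([2.0, 2.0, 2.0], [2.0, 2.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(isens.DegenerateDataError):
            isens.mann_whitney([1.0], [2.0, 3.0])
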