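"""The five multi-label metrics, subsampling protocol and t-tests."""

import numpy as np
import pytest

from prmftp.metrics import (
    MetricReport,
    compare_methods_ttest,
    evaluate_multilabel,
    format_report_table,
    per_class_coverage,
    significance_stars,
    subsample_evaluate,
)


def bruteforce_metrics(truth, predicted):
    """Independent set-theoretic recomputation of all five metrics."""
    n, m = truth.shape
    prec = cov = acc = atrue = afalse = 0.0
    for i in range(n):
        L = {j for j in range(m) if truth[i, j]}
        Lp = {j for j in range(m) if predicted[i, j]}
        inter, union = L & Lp, L | Lp
        prec += len(inter) / len(Lp) if Lp else (1.0 if not L else 0.0)
        cov += len(inter) / len(L) if L else 1.0
        acc += len(inter) / len(union) if union else 1.0
        atrue += 1.0 if L == Lp else 0.0
        afalse += (len(union) - len(inter)) / m
    return np.array([prec, cov, acc, atrue, afalse]) / n


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        y = rng.integers(0, 2, size=(10, 6))
        y[:, 0] = 1  # no empty label sets
        rep = evaluate_multilabel(y, y)
        assert rep.precision == rep.coverage == rep.accuracy == rep.absolute_true == 1.0
        assert rep.absolute_false == 0.0

    def test_worked_two_sample_example(self):
        m = 21
        truth = np.zeros((2, m)); pred = np.zeros((2, m))
        truth[0, [0, 1]] = 1   # {A,B}
        pred[0, 0] = 1         # {A}
        truth[1, 2] = 1        # {C}
        pred[1, 2] = 1         # {C}
        rep = evaluate_multilabel(truth, pred)
        assert rep.precision == pytest.approx(1.0)
        assert rep.coverage == pytest.approx(0.75)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.absolute_true == pytest.approx(0.5)
        assert rep.absolute_false == pytest.approx(1 / 42)

    def test_disjoint_predictions(self):
        truth = np.array([[1, 0, 0], [0, 1, 1]])
        pred = np.array([[0, 1, 0], [1, 0, 0]])
        rep = evaluate_multilabel(truth, pred)
        assert rep.precision == rep.coverage == rep.accuracy == rep.absolute_true == 0.0
        assert rep.absolute_false == pytest.approx(np.mean([2 / 3, 3 / 3]))

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 21))
            m = int(rng.integers(1, 11))
            truth = rng.integers(0, 2, size=(n, m))
            pred = rng.integers(0, 2, size=(n, m))
            rep = evaluate_multilabel(truth, pred)
            np.testing.assert_allclose(rep.as_array(), bruteforce_metrics(truth, pred), atol=1e-12)

    def test_permutation_invariance(self, rng):
        truth = rng.integers(0, 2, size=(12, 7))
        pred = rng.integers(0, 2, size=(12, 7))
        rows = rng.permutation(12); cols = rng.permutation(7)
        a = evaluate_multilabel(truth, pred)
        b = evaluate_multilabel(truth[rows][:, cols], pred[rows][:, cols])
        np.testing.assert_allclose(a.as_array(), b.as_array())

    def test_adding_correct_label_never_hurts_coverage_or_accuracy(self, rng):
        for _ in range(50):
            truth = rng.integers(0, 2, size=(8, 6))
            pred = rng.integers(0, 2, size=(8, 6))
            missing = np.argwhere((truth == 1) & (pred == 0))
            if missing.size == 0:
                continue
            i, j = missing[rng.integers(0, len(missing))]
            before = evaluate_multilabel(truth, pred)
            pred2 = pred.copy(); pred2[i, j] = 1
            after = evaluate_multilabel(truth, pred2)
            assert after.coverage >= before.coverage
            assert after.accuracy >= before.accuracy

    def test_absolute_true_bounded_by_accuracy(self, rng):
        for _ in range(50):
            truth = rng.integers(0, 2, size=(6, 5))
            pred = rng.integers(0, 2, size=(6, 5))
            rep = evaluate_multilabel(truth, pred)
            assert rep.absolute_true <= rep.accuracy <= 1.0
            assert 0.0 <= rep.absolute_false <= 1.0

    def test_shape_and_value_validation(self):
        with pytest.raises(ValueError):
            evaluate_multilabel(np.ones((2, 3)), np.ones((3, 2)))
        with pytest.raises(ValueError):
            evaluate_multilabel(np.full((2, 2), 0.5), np.ones((2, 2)))


class TestPerClassCoverage:
    def test_recall_per_column(self):
        truth = np.array([[1, 0], [1, 0], [0, 1]])
        pred = np.array([[1, 0], [0, 0], [0, 1]])
        cov = per_class_coverage(truth, pred)
        assert cov[0] == pytest.approx(0.5) and cov[1] == pytest.approx(1.0)

    def test_absent_class_is_nan(self):
        cov = per_class_coverage(np.array([[1, 0]]), np.array([[1, 1]]))
        assert np.isnan(cov[1])


class TestSubsample:
    def test_full_fraction_single_rep_equals_plain_evaluation(self, rng):
        probs = rng.uniform(size=(15, 4))
        truth = rng.integers(0, 2, size=(15, 4))
        mean, reps = subsample_evaluate(probs, truth, fraction=1.0, reps=1, seed=3)
        direct = evaluate_multilabel(truth, (probs >= 0.5).astype(int))
        np.testing.assert_allclose(mean.as_array(), direct.as_array())
        assert len(reps) == 1

    def test_seed_reproducibility(self, rng):
        probs = rng.uniform(size=(30, 5))
        truth = rng.integers(0, 2, size=(30, 5))
        a = subsample_evaluate(probs, truth, seed=9)
        b = subsample_evaluate(probs, truth, seed=9)
        np.testing.assert_array_equal(a[0].as_array(), b[0].as_array())

    def test_mean_within_rep_range(self, rng):
        probs = rng.uniform(size=(40, 5))
        truth = rng.integers(0, 2, size=(40, 5))
        mean, reps = subsample_evaluate(probs, truth, reps=5, seed=1)
        arr = np.array([r.as_array() for r in reps])
        assert np.all(mean.as_array() >= arr.min(axis=0) - 1e-12)
        assert np.all(mean.as_array() <= arr.max(axis=0) + 1e-12)

    def test_zero_subset_raises(self, rng):
        with pytest.raises(ValueError):
            subsample_evaluate(np.ones((3, 2)), np.ones((3, 2)), fraction=0.1)


class TestTTest:
    def test_identical_samples_t_zero(self):
        t, p = compare_methods_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert t == 0.0 and p == 1.0

    def test_constant_shift_paired_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_methods_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], paired=True)

    def test_unpaired_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        t, p = compare_methods_ttest(a, b, paired=False)
        # pooled two-sample t with equal variances
        sp = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2)
        expected = (np.mean(a) - np.mean(b)) / (sp * np.sqrt(2 / 3))
        assert t == pytest.approx(expected)
        assert 0 < p < 1

    def test_minimum_observations(self):
        with pytest.raises(ValueError):
            compare_methods_ttest([1.0], [2.0])

    def test_stars_mapping(self):
        assert significance_stars(0.3) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.00005) == "****"


def test_report_table_layout(rng):
    rep = MetricReport(0.626, 0.574, 0.570, 0.524, 0.034)
    table = format_report_table({"full": rep})
    assert "Precision" in table and "Absolute false" in table
    assert "0.626" in table.splitlines()[1]
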