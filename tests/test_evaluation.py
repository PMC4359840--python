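import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adscreen import (
    BayesNetClassifier,
    CohortSpec,
    TotalScoreCutoffClassifier,
    bootstrap_632,
    cross_validate,
    cutoff_baseline,
    friedman_test,
    generate_cohort,
    metrics_from_confusion,
    reduction_ratio,
    wilcoxon_signed_rank,
)
from adscreen.evaluation import EvaluationError
from conftest import ConstantClassifier, FirstItemBandClassifier, MajorityClassifier


class TestConfusionMetrics:
    def test_perfect_diagonal(self):
        m = metrics_from_confusion(np.diag([10, 10, 10]))
        assert m["accuracy"] == 1.0
        assert all(v == 1.0 for v in m["recall"].values())
        assert all(v == 1.0 for v in m["precision"].values())

    def test_two_class_hand_arithmetic(self):
        m = metrics_from_confusion(np.array([[8, 2], [4, 6]]))
        assert m["recall"]["0"] == pytest.approx(0.8)
        assert m["recall"]["1"] == pytest.approx(0.6)
        assert m["precision"]["0"] == pytest.approx(8 / 12)
        assert m["precision"]["1"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.7)

    def test_zero_row_recall_undefined(self):
        m = metrics_from_confusion(np.array([[0, 0], [1, 9]]))
        assert m["recall"]["0"] is None
        assert m["accuracy"] == pytest.approx(0.9)

    def test_rejects_non_square_and_negative(self):
        with pytest.raises(EvaluationError):
            metrics_from_confusion(np.ones((2, 3)))
        with pytest.raises(EvaluationError):
            metrics_from_confusion(np.array([[1, -1], [0, 1]]))


@pytest.fixture(scope="module")
def cohort():
    table, truth = generate_cohort(
        CohortSpec(n_subjects=200, n_items=8, n_discriminative=4, seed=31)
    )
    return table


class TestCrossValidate:
    def test_majority_classifier_accuracy(self, cohort):
        rep = cross_validate(cohort, MajorityClassifier(), k=5, repetitions=2, seed=0)
        majority = pd.Series(cohort.y()).value_counts(normalize=True).max()
        assert rep.accuracy == pytest.approx(majority, abs=0.02)

    def test_separable_cohort_perfect(self):
        t, _ = generate_cohort(CohortSpec(n_subjects=200, n_items=6,
                                          n_discriminative=3, separable=True,
                                          noise=0.0, seed=5))
        rep = cross_validate(t, BayesNetClassifier(), k=5, repetitions=2, seed=1)
        assert rep.accuracy == pytest.approx(1.0)

    def test_deterministic_given_seed(self, cohort):
        a = cross_validate(cohort, BayesNetClassifier(), k=5, repetitions=2, seed=7)
        b = cross_validate(cohort, BayesNetClassifier(), k=5, repetitions=2, seed=7)
        assert a.per_repetition_accuracy == b.per_repetition_accuracy
        pd.testing.assert_frame_equal(a.confusion, b.confusion)

    def test_small_class_raises(self):
        t, _ = generate_cohort(CohortSpec(n_subjects=15, n_items=3,
                                          n_discriminative=1, seed=2))
        with pytest.raises(EvaluationError, match="smaller k"):
            cross_validate(t, MajorityClassifier(), k=10)

    def test_confusion_totals_match_cases(self, cohort):
        rep = cross_validate(cohort, MajorityClassifier(), k=5, repetitions=3, seed=0)
        assert rep.confusion.to_numpy().sum() == pytest.approx(cohort.n_objects)


class TestBootstrap632:
    def test_zero_error_classifier_scores_one(self):
        t, _ = generate_cohort(CohortSpec(n_subjects=150, n_items=4,
                                          n_discriminative=2, separable=True,
                                          noise=0.0, seed=9))
        rep = bootstrap_632(t, FirstItemBandClassifier(), repetitions=5, seed=3)
        assert rep.accuracy == pytest.approx(1.0)

    def test_convex_combination_identity(self, cohort):
        rep = bootstrap_632(cohort, BayesNetClassifier(), repetitions=4, seed=11)
        for comp, acc in zip(rep.extras["error_components"],
                             rep.per_repetition_accuracy):
            expected = 1 - (0.368 * comp["err_train"] + 0.632 * comp["err_oob"])
            assert acc == pytest.approx(expected, abs=1e-12)

    def test_reproducible_given_seed(self, cohort):
        a = bootstrap_632(cohort, BayesNetClassifier(), repetitions=3, seed=4)
        b = bootstrap_632(cohort, BayesNetClassifier(), repetitions=3, seed=4)
        assert a.per_repetition_accuracy == b.per_repetition_accuracy

    def test_oob_fraction_near_nominal(self):
        rng = np.random.default_rng(0)
        n = 500
        fracs = [
            np.setdiff1d(np.arange(n), rng.integers(0, n, n)).size / n
            for _ in range(300)
        ]
        assert np.mean(fracs) == pytest.approx(1 - 0.632, abs=0.01)


class TestFriedman:
    def test_identical_groups_statistic_zero(self):
        res = friedman_test(np.ones((5, 3)))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n, k = int(rng.integers(3, 10)), int(rng.integers(3, 6))
            mat = rng.integers(0, 6, size=(n, k)).astype(float)
            mine = friedman_test(mat)
            try:
                ref = stats.friedmanchisquare(*[mat[:, j] for j in range(k)])
            except ValueError:
                continue  # fully tied matrix: reference refuses
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)
            assert mine.df == k - 1

    def test_textbook_example(self):
        # 4 blocks x 3 groups, no ties
        mat = np.array([[9, 4, 1], [9.5, 3, 1.5], [5, 7, 2], [7.5, 6, 3]])
        ref = stats.friedmanchisquare(mat[:, 0], mat[:, 1], mat[:, 2])
        mine = friedman_test(mat)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-9)

    def test_mean_ranks_reported(self):
        mat = np.array([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        res = friedman_test(mat, group_labels=["lo", "mid", "hi"])
        assert res.mean_ranks == {"lo": 1.0, "mid": 2.0, "hi": 3.0}


class TestWilcoxon:
    def test_identical_samples(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_five_positive_differences_one_sided(self):
        res = wilcoxon_signed_rank([2, 4, 6, 8, 10], [1, 2, 3, 4, 5],
                                   alternative="greater")
        assert res.p_value == pytest.approx(1 / 32)

    def test_exact_matches_reference(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(8, 26))
            x, y = rng.normal(size=n), rng.normal(size=n)
            mine = wilcoxon_signed_rank(x, y)
            ref = stats.wilcoxon(x, y, method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)
            assert mine.statistic == pytest.approx(ref.statistic)

    def test_approx_matches_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(30, 60))
            x, y = rng.normal(size=n), rng.normal(size=n)
            mine = wilcoxon_signed_rank(x, y, correction=True)
            ref = stats.wilcoxon(x, y, method="approx", correction=True)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_symmetric_null_type_one_error(self):
        rng = np.random.default_rng(4)
        rejections = 0
        trials = 2000
        for _ in range(trials):
            d = rng.normal(size=30)
            if wilcoxon_signed_rank(d).p_value < 0.05:
                rejections += 1
        rate = rejections / trials
        se = np.sqrt(0.05 * 0.95 / trials)
        assert abs(rate - 0.05) < 4 * se


class TestReductionRatio:
    def test_paper_scale_example(self):
        assert reduction_ratio(34, 10) == pytest.approx(70.59, abs=0.005)

    def test_no_reduction(self):
        assert reduction_ratio(7, 7) == 0.0

    def test_half(self):
        assert reduction_ratio(10, 5) == 50.0

    def test_rejects_growth(self):
        with pytest.raises(EvaluationError):
            reduction_ratio(5, 6)


class TestCutoffBaseline:
    @pytest.mark.parametrize(
        "score,instrument,expected",
        [
            (27, "MMSE", "Normal"),
            (30, "MMSE", "Normal"),
            (26, "MMSE", "MCI"),
            (19, "MMSE", "MCI"),
            (18, "MMSE", "AD"),
            (9, "MMSE", "AD"),
            (26, "MoCA", "Normal"),
            (25, "MoCA", "MCI"),
            (18, "MoCA", "MCI"),
            (17, "MoCA", "AD"),
            (0, "MoCA", "AD"),
        ],
    )
    def test_staging(self, score, instrument, expected):
        assert cutoff_baseline(score, instrument) == expected

    def test_out_of_range(self):
        with pytest.raises(EvaluationError):
            cutoff_baseline(31, "MMSE")

    def test_unknown_instrument(self):
        with pytest.raises(EvaluationError):
            cutoff_baseline(20, "CDR")

    def test_total_score_classifier_on_separable_cohort(self):
        t, _ = generate_cohort(CohortSpec(n_subjects=200, n_items=6,
                                          n_discriminative=6, separable=True,
                                          noise=0.0, seed=17))
        clf = TotalScoreCutoffClassifier("MoCA")
        clf.fit(t.X(), t.y())
        pred = clf.predict(t.X())
        assert set(pred) <= {"Normal", "MCI", "AD"}
        assert (pred == t.y()).mean() > 1 / 3  # better than chance
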