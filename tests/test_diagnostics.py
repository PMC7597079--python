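"""ROC analysis, cutoff selection, performance metrics and the DeLong test."""

import numpy as np
import pandas as pd
import pytest

import usentropy as u
from usentropy.diagnostics import delong_placements

from .conftest import brute_force_auroc

TABLE1_COUNTS = {"normal": 79, "mild": 74, "moderate": 35, "severe": 17}


def _cohort_grades():
    grades = []
    for g, n in TABLE1_COUNTS.items():
        grades += [g] * n
    return grades


class TestBinarize:
    @pytest.mark.parametrize(
        "criterion,n_pos,n_neg",
        [("mild", 126, 79), ("moderate", 52, 153), ("severe", 17, 188)],
    )
    def test_cohort_partition(self, criterion, n_pos, n_neg):
        labels = u.binarize(_cohort_grades(), criterion)
        assert labels.sum() == n_pos
        assert (labels == 0).sum() == n_neg

    def test_degenerate_task_warned(self):
        with pytest.warns(UserWarning, match="degenerate"):
            u.binarize(["normal", "normal"], "severe")

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError, match="unknown grade"):
            u.binarize(["normal", "steatotic"], "mild")


class TestSplit:
    def test_cohort_split_sizes(self):
        table = pd.DataFrame({"subject_id": range(205), "grade": _cohort_grades()})
        labels = u.binarize(table.grade, "mild")
        tr, te = u.split_train_test(table, labels, ratio=4, seed=0)
        assert (len(tr), len(te)) == (164, 41)

    def test_tiny_split(self):
        table = pd.DataFrame({"x": range(5)})
        labels = np.array([0, 0, 0, 1, 1])
        tr, te = u.split_train_test(table, labels, ratio=4, seed=1, stratify=False)
        assert (len(tr), len(te)) == (4, 1)

    def test_seed_determinism(self):
        table = pd.DataFrame({"x": range(50)})
        labels = np.array([0, 1] * 25)
        a = u.split_train_test(table, labels, seed=7)
        b = u.split_train_test(table, labels, seed=7)
        assert a[0].equals(b[0]) and a[1].equals(b[1])


class TestROC:
    def test_perfect_separation(self):
        roc = u.roc_analysis([1, 2, 10, 11], [0, 0, 1, 1])
        assert roc.auroc == 1.0
        assert roc.degenerate_ci  # zero DeLong variance flagged

    @pytest.mark.parametrize(
        "scores,labels,expected",
        [([1, 2, 3, 4], [0, 0, 1, 1], 1.0), ([1, 3, 2, 4], [0, 0, 1, 1], 0.75)],
    )
    def test_small_exact_cases(self, scores, labels, expected):
        roc = u.roc_analysis(scores, labels, with_ci=False)
        assert roc.auroc == pytest.approx(expected)
        assert roc.auroc == pytest.approx(brute_force_auroc(scores, labels))

    def test_trapezoid_equals_pair_count_with_ties(self):
        """AUROC with tie grouping equals Mann-Whitney on random instances."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(4, 21)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            roc = u.roc_analysis(scores, labels, with_ci=False)
            assert roc.auroc == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=4000)
        scores = rng.normal(size=4000)
        roc = u.roc_analysis(scores, labels, with_ci=False)
        assert roc.auroc == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        labels = np.array([0] * 20 + [1] * 20)
        scores = rng.normal(size=40) + labels
        a = u.roc_analysis(scores, labels, with_ci=False).auroc
        b = u.roc_analysis(np.exp(3 * scores), labels, with_ci=False).auroc
        assert a == pytest.approx(b, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            u.roc_analysis([1, 2], [1, 1])


class TestCutoff:
    def test_perfect_separation_hits_corner(self):
        roc = u.roc_analysis([1, 2, 10, 11], [0, 0, 1, 1], with_ci=False)
        cut = u.optimal_cutoff(roc)
        pred = u.classify([1, 2, 10, 11], cut)
        np.testing.assert_array_equal(pred, [0, 0, 1, 1])

    def test_exhaustive_vertex_evaluation(self):
        """Chosen vertex minimizes sqrt(fpr^2 + (1-tpr)^2) over all vertices."""
        rng = np.random.default_rng(6)
        labels = np.array([0] * 15 + [1] * 15)
        scores = rng.normal(size=30) + 0.8 * labels
        roc = u.roc_analysis(scores, labels, with_ci=False)
        cut = u.optimal_cutoff(roc)
        d = np.sqrt(roc.fpr**2 + (1 - roc.tpr) ** 2)
        i = np.flatnonzero(roc.thresholds == cut)[0]
        assert d[i] == pytest.approx(d.min())

    def test_tie_breaks_toward_lower_fpr(self):
        # symmetric ROC: vertices (0, 0.5) and (0.5, 1) are equidistant to (0,1)
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 1, 0, 1]
        roc = u.roc_analysis(scores, labels, with_ci=False)
        cut = u.optimal_cutoff(roc)
        i = np.flatnonzero(roc.thresholds == cut)[0]
        d = np.sqrt(roc.fpr**2 + (1 - roc.tpr) ** 2)
        ties = np.flatnonzero(np.isclose(d, d.min()))
        assert roc.fpr[i] == roc.fpr[ties].min()

    def test_classify_conventions(self):
        scores = [1.0, 2.0, 3.0]
        assert u.classify(scores, 0.5).tolist() == [1, 1, 1]
        assert u.classify(scores, 5.0).tolist() == [0, 0, 0]
        assert u.classify(scores, 2.0).tolist() == [0, 1, 1]  # ties positive


class TestPerformance:
    def test_hand_confusion_matrix(self):
        pred = [1] * 9 + [0] * 2 + [1] * 1 + [0] * 8
        labels = [1] * 11 + [0] * 9
        m = u.performance(pred, labels)
        assert (m.tp, m.fn, m.fp, m.tn) == (9, 2, 1, 8)
        assert m.sensitivity == pytest.approx(9 / 11)
        assert m.specificity == pytest.approx(8 / 9)
        assert m.accuracy == pytest.approx(17 / 20)
        assert m.precision == pytest.approx(0.9)
        assert m.f1 == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11))

    def test_perfect_prediction(self):
        m = u.performance([0, 1, 1], [0, 1, 1])
        assert (m.accuracy, m.sensitivity, m.specificity, m.f1) == (1, 1, 1, 1)

    def test_degenerate_all_negative(self):
        m = u.performance([0, 0, 0], [0, 1, 1])
        assert m.sensitivity == 0.0
        assert np.isnan(m.precision)


class TestDeLong:
    def test_placements_toy_case(self):
        auroc, v10, v01 = delong_placements([1, 3, 2, 4], [0, 0, 1, 1])
        assert auroc == pytest.approx(0.75)
        np.testing.assert_allclose(sorted(v10), [0.5, 1.0])
        np.testing.assert_allclose(sorted(v01), [0.5, 1.0])

    def test_perfect_separation_zero_variance(self):
        _, var, ci = u.delong_variance([1, 2, 10, 11], [0, 0, 1, 1])
        assert var == 0.0
        assert ci[0] == ci[1] == 1.0

    def test_matches_pROC_reference(self):
        """Frozen reference values from an independent DeLong implementation
        (R pROC, var/ci.auc/roc.test on the same synthetic fixture)."""
        rng = np.random.default_rng(123)
        n = 30
        y = np.array([0] * 15 + [1] * 15)
        a = y * 1.0 + rng.normal(0, 1, n)
        b = y * 0.8 + 0.5 * a + rng.normal(0, 1, n)
        auroc, var, ci = u.delong_variance(a, y)
        assert auroc == pytest.approx(0.8577777778, abs=1e-10)
        assert var == pytest.approx(0.0054067019, abs=1e-10)
        assert ci[0] == pytest.approx(0.713661, abs=1e-6)
        z, p = u.delong_test(a, b, y)
        assert z == pytest.approx(0.875190, abs=1e-6)
        assert p == pytest.approx(0.3814705612, abs=1e-10)

    def test_self_comparison_degenerate(self):
        rng = np.random.default_rng(3)
        y = np.array([0] * 10 + [1] * 10)
        s = rng.normal(size=20) + y
        with pytest.warns(UserWarning, match="zero variance"):
            z, p = u.delong_test(s, s, y)
        assert (z, p) == (0.0, 1.0)

    def test_monotone_transform_gives_p_one(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 12 + [1] * 12)
        s = rng.normal(size=24) + y
        with pytest.warns(UserWarning, match="zero variance"):
            z, p = u.delong_test(np.exp(s), s, y)
        assert p == 1.0

    def test_variance_shrinks_as_one_over_n(self):
        """DeLong variance scales ~1/n: doubling n roughly halves it (in the mean)."""
        rng = np.random.default_rng(9)
        ratios = []
        for _ in range(200):
            y1 = np.array([0] * 30 + [1] * 30)
            s1 = rng.normal(size=60) + y1
            y2 = np.array([0] * 60 + [1] * 60)
            s2 = rng.normal(size=120) + y2
            _, v1, _ = u.delong_variance(s1, y1)
            _, v2, _ = u.delong_variance(s2, y2)
            ratios.append(v1 / v2)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.2)


class TestEstimatorAPI:
    def test_fit_predict_roundtrip(self):
        rng = np.random.default_rng(5)
        y = np.array([0] * 40 + [1] * 40)
        X = (rng.normal(size=80) + 2.0 * y).reshape(-1, 1)
        clf = u.ROCThresholdClassifier().fit(X, y)
        assert clf.auroc_ > 0.9
        assert clf.predict(X).shape == y.shape
        assert set(np.unique(clf.predict(X))) <= {0, 1}
        assert clf.ci95_[0] < clf.auroc_ <= 1.0

    def test_sklearn_clone_compat(self):
        from sklearn.base import clone

        clf = u.ROCThresholdClassifier(with_ci=False)
        assert clone(clf).get_params() == clf.get_params()


class TestEvaluatePipeline:
    def test_report_schema_and_separable_cohort(self):
        rng = np.random.default_rng(8)
        grades = _cohort_grades()
        level = {"normal": 0.0, "mild": 1.0, "moderate": 2.0, "severe": 3.0}
        scores = np.array([level[g] for g in grades]) + rng.normal(0, 0.2, len(grades))
        table = pd.DataFrame(
            {"subject_id": range(205), "grade": grades, "entropy_mean": scores}
        )
        report = u.evaluate_pipeline(table, seed=0)
        expected_cols = {
            "criterion", "cutoff", "accuracy", "sensitivity", "specificity",
            "precision", "recall", "f1", "auroc", "ci95_low", "ci95_high",
        }
        assert expected_cols <= set(report.columns)
        assert list(report.criterion) == [">=mild", ">=moderate", ">=severe"]
        assert (report.n_train == 164).all() and (report.n_test == 41).all()
        assert (report.auroc > 0.95).all()
        assert report.cutoff.is_monotonic_increasing
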