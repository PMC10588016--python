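"""Confusion-matrix metrics: worked example, brute-force oracle, invariants."""

import itertools
import warnings

import numpy as np
import pytest

from morsecg import (
    ConfusionMatrix,
    OneVsRestCounts,
    compute_metrics,
    confusion_matrix,
    evaluate,
    macro_average,
    one_vs_rest,
    overall_accuracy,
)

CLASSES = ["ARR", "CHF", "NSR"]

# The published per-class one-vs-rest counts of the worked example
# (360 test segments, 120 per class).
WORKED_COUNTS = {
    "ARR": dict(tp=120, tn=238, fp=2, fn=0),
    "CHF": dict(tp=118, tn=240, fp=0, fn=2),
    "NSR": dict(tp=119, tn=239, fp=1, fn=1),
}
# Rows = predicted, columns = actual.
WORKED_MATRIX = np.array([[120, 1, 1], [0, 118, 0], [0, 1, 119]])


def test_worked_matrix_is_unique_given_counts():
    """Exhaustive check: exactly one 3x3 matrix with 120-per-class columns
    reproduces all twelve one-vs-rest counts."""
    solutions = []
    # diagonal fixed by TP; six off-diagonal entries bounded by the FP totals
    for off in itertools.product(range(3), repeat=6):
        m = np.zeros((3, 3), dtype=int)
        for i, c in enumerate(CLASSES):
            m[i, i] = WORKED_COUNTS[c]["tp"]
        m[0, 1], m[0, 2], m[1, 0], m[1, 2], m[2, 0], m[2, 1] = off
        if not all(m[:, j].sum() == 120 for j in range(3)):
            continue
        cm = ConfusionMatrix(m, CLASSES)
        ok = all(
            one_vs_rest(cm, c)
            == OneVsRestCounts(**WORKED_COUNTS[c])
            for c in CLASSES
        )
        if ok:
            solutions.append(m)
    assert len(solutions) == 1
    np.testing.assert_array_equal(solutions[0], WORKED_MATRIX)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = [c for c in CLASSES for _ in range(120)]
        cm = confusion_matrix(y, y, CLASSES)
        np.testing.assert_array_equal(cm.counts, np.diag([120, 120, 120]))
        assert cm.total == 360

    def test_rows_predicted_columns_actual(self):
        cm = confusion_matrix(["ARR"], ["CHF"], CLASSES)
        assert cm.counts[1, 0] == 1  # predicted CHF (row), actual ARR (col)

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_matrix([], [], CLASSES)
        with pytest.raises(ValueError, match="XXX"):
            confusion_matrix(["XXX"], ["ARR"], CLASSES)
        with pytest.raises(ValueError, match="length"):
            confusion_matrix(["ARR"], ["ARR", "CHF"], CLASSES)

    def test_matches_sklearn_transposed(self, rng):
        from sklearn.metrics import confusion_matrix as sk_cm

        y_true = rng.choice(CLASSES, 200)
        y_pred = rng.choice(CLASSES, 200)
        ours = confusion_matrix(y_true, y_pred, CLASSES).counts
        theirs = sk_cm(y_true, y_pred, labels=CLASSES)  # rows = true
        np.testing.assert_array_equal(ours, theirs.T)


class TestOneVsRest:
    @pytest.mark.parametrize("cls", CLASSES)
    def test_worked_example_counts(self, cls):
        cm = ConfusionMatrix(WORKED_MATRIX, CLASSES)
        assert one_vs_rest(cm, cls) == OneVsRestCounts(**WORKED_COUNTS[cls])

    def test_identity_matrix_no_errors(self):
        cm = ConfusionMatrix(np.diag([5, 6, 7]), CLASSES)
        for c in CLASSES:
            counts = one_vs_rest(cm, c)
            assert counts.fp == 0 and counts.fn == 0

    def test_count_identities(self):
        cm = ConfusionMatrix(WORKED_MATRIX, CLASSES)
        for i, c in enumerate(CLASSES):
            counts = one_vs_rest(cm, c)
            assert counts.total == cm.total
            assert counts.tp + counts.fn == cm.counts[:, i].sum()
            assert counts.tp + counts.fp == cm.counts[i, :].sum()

    def test_unknown_class_rejected(self):
        cm = ConfusionMatrix(WORKED_MATRIX, CLASSES)
        with pytest.raises(ValueError, match="VF"):
            one_vs_rest(cm, "VF")


class TestComputeMetrics:
    def test_chf_row(self):
        m = compute_metrics(OneVsRestCounts(tp=118, tn=240, fp=0, fn=2))
        assert round(m["sensitivity"], 1) == 98.3
        assert round(m["specificity"], 1) == 100.0
        assert round(m["precision"], 1) == 100.0

    def test_arr_row(self):
        m = compute_metrics(OneVsRestCounts(tp=120, tn=238, fp=2, fn=0))
        assert round(m["sensitivity"], 1) == 100.0
        assert round(m["precision"], 1) == 98.4

    def test_sensitivity_equals_recall_always(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 50, 4)
            if tp + fn == 0:
                continue
            m = compute_metrics(OneVsRestCounts(int(tp), int(tn), int(fp), int(fn)))
            assert m["sensitivity"] == m["recall"]

    def test_chf_f_measure_from_raw_counts(self):
        # from raw counts F1 = 2*100*98.333/198.333 = 99.16, not the
        # pre-rounded 99.1; the toolkit reports the raw-count value
        m = compute_metrics(OneVsRestCounts(tp=118, tn=240, fp=0, fn=2))
        assert m["f_measure"] == pytest.approx(99.15966386554622)
        assert round(m["f_measure"], 1) == 99.2

    def test_zero_denominator_gives_nan_with_warning(self):
        with pytest.warns(UserWarning, match="precision"):
            m = compute_metrics(OneVsRestCounts(tp=0, tn=10, fp=0, fn=5))
        assert np.isnan(m["precision"])
        assert not np.isnan(m["sensitivity"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            OneVsRestCounts(tp=-1, tn=0, fp=0, fn=0)


class TestOverallAccuracyAndMacro:
    def test_worked_example_accuracy(self):
        cm = ConfusionMatrix(WORKED_MATRIX, CLASSES)
        assert round(overall_accuracy(cm), 1) == 99.2

    def test_identity_and_all_wrong(self):
        assert overall_accuracy(ConfusionMatrix(np.diag([3, 3, 3]), CLASSES)) == 100.0
        cm2 = ConfusionMatrix(np.array([[0, 5], [5, 0]]), ["A", "B"])
        assert overall_accuracy(cm2) == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overall_accuracy(ConfusionMatrix(np.zeros((2, 2), dtype=int), ["A", "B"]))

    def test_accuracy_invariant_under_class_permutation(self):
        perm = [2, 0, 1]
        permuted = WORKED_MATRIX[np.ix_(perm, perm)]
        a = overall_accuracy(ConfusionMatrix(WORKED_MATRIX, CLASSES))
        b = overall_accuracy(ConfusionMatrix(permuted, [CLASSES[i] for i in perm]))
        assert a == pytest.approx(b)

    def test_macro_averages_of_worked_example(self):
        per_class = {
            c: compute_metrics(OneVsRestCounts(**WORKED_COUNTS[c])) for c in CLASSES
        }
        macro = macro_average(per_class)
        assert round(macro["specificity"], 1) == 99.6
        assert round(macro["sensitivity"], 1) == 99.2
        assert round(macro["precision"], 1) == 99.2
        assert round(macro["recall"], 1) == 99.2
        assert round(macro["f_measure"], 1) == 99.2

    def test_macro_mean_is_of_unrounded_values(self):
        assert round(np.mean([100.0, 98.0 + 1 / 3, 99.0 + 1 / 6]), 1) == 99.2

    def test_identical_reports_average_to_themselves(self):
        m = compute_metrics(OneVsRestCounts(10, 10, 2, 3))
        macro = macro_average({"A": m, "B": dict(m)})
        for k, v in macro.items():
            assert v == pytest.approx(m[k])


class TestBruteForceOracle:
    def test_matrix_path_equals_direct_enumeration(self, rng):
        """Metrics from the confusion matrix equal metrics counted item by item."""
        for trial in range(20):
            k = int(rng.integers(2, 5))
            classes = [f"C{i}" for i in range(k)]
            n = int(rng.integers(max(k, 2), 31))
            y_true = [classes[i] for i in rng.integers(0, k, n)]
            y_pred = [classes[i] for i in rng.integers(0, k, n)]
            cm = confusion_matrix(y_true, y_pred, classes)
            for c in classes:
                counts = one_vs_rest(cm, c)
                tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
                fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
                fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
                tn = sum(1 for t, p in zip(y_true, y_pred) if t != c and p != c)
                assert counts == OneVsRestCounts(tp, tn, fp, fn)
            acc = 100.0 * np.mean([t == p for t, p in zip(y_true, y_pred)])
            assert overall_accuracy(cm) == pytest.approx(acc)


class TestReport:
    def test_evaluate_end_to_end_table(self):
        y_true = (
            ["ARR"] * 120 + ["CHF"] * 120 + ["NSR"] * 120
        )
        y_pred = (
            ["ARR"] * 120
            + ["ARR"] * 1 + ["CHF"] * 118 + ["NSR"] * 1
            + ["ARR"] * 1 + ["NSR"] * 119
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no undefined metrics expected
            report = evaluate(y_true, y_pred, CLASSES)
        np.testing.assert_array_equal(
            np.array([[report.per_class_counts[c].tp for c in CLASSES]]),
            [[120, 118, 119]],
        )
        assert round(report.overall_accuracy, 1) == 99.2
        frame = report.to_frame()
        assert list(frame.columns) == ["Class", "TP", "TN", "FP", "FN", "Se", "Sp", "Pr", "Re", "F1"]
        assert frame.iloc[-1]["Class"] == "Avg"
        assert frame.iloc[-1]["Sp"] == 99.6
        d = report.to_dict()
        assert d["per_class"]["CHF"]["tp"] == 118
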