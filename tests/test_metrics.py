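"""The patch-to-scan / whole-scan / total accuracy protocol and reports."""

import logging

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from histofuse import (
    EvaluationReport,
    PredictionSet,
    comparison_table,
    confusion_matrix,
    patch_to_scan_accuracy,
    per_class_report,
    total_accuracy,
    whole_scan_accuracy,
)
from histofuse.metrics import (
    confusion_to_csv,
    render_comparison_table,
    render_per_class_table,
)


def _brute_force_confusion(truth, pred, k):
    mat = [[0] * k for _ in range(k)]
    for t, p in zip(truth, pred):
        mat[t][p] += 1
    return np.array(mat)


class TestConfusionMatrix:
    def test_direct_count(self):
        got = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(got, [[1, 1], [0, 1]])

    def test_perfect_predictions_are_diagonal(self, rng):
        truth = rng.integers(0, 5, size=40)
        got = confusion_matrix(truth, truth, 5)
        assert (got == np.diag(np.bincount(truth, minlength=5))).all()

    def test_matches_brute_force_tally(self, rng):
        truth = rng.integers(0, 24, size=500)
        pred = rng.integers(0, 24, size=500)
        np.testing.assert_array_equal(
            confusion_matrix(truth, pred, 24),
            _brute_force_confusion(truth, pred, 24),
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], 2)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 2)


class TestPatchToScan:
    def test_all_correct_is_one(self):
        assert patch_to_scan_accuracy(np.diag([3, 5, 2])) == 1.0

    def test_equals_trace_over_total(self, rng):
        mat = rng.integers(0, 20, size=(6, 6))
        expected = mat.trace() / mat.sum()
        assert patch_to_scan_accuracy(mat) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            patch_to_scan_accuracy(np.zeros((3, 3)))


class TestWholeScan:
    def test_all_correct_is_one(self):
        assert whole_scan_accuracy(np.diag([3, 5, 2])) == 1.0

    def test_hand_enumeration(self):
        # supports (2, 4, 4), correct (1, 4, 0) -> (0.5 + 1 + 0)/3
        mat = np.array([[1, 1, 0], [0, 4, 0], [4, 0, 0]])
        assert whole_scan_accuracy(mat) == pytest.approx(0.5)

    def test_equals_mean_per_class_recall(self, rng):
        mat = rng.integers(1, 15, size=(8, 8))
        report = per_class_report(mat)
        assert whole_scan_accuracy(mat) == pytest.approx(
            report["recall"].mean())

    def test_zero_support_classes_excluded_with_warning(self, caplog):
        mat = np.array([[3, 0, 0], [0, 0, 0], [1, 0, 1]])
        with caplog.at_level(logging.WARNING, logger="histofuse"):
            got = whole_scan_accuracy(mat)
        assert got == pytest.approx((1.0 + 0.5) / 2)
        assert any("zero test" in r.message for r in caplog.records)

    def test_all_rows_empty_rejected(self):
        with pytest.raises(ValueError):
            whole_scan_accuracy(np.zeros((2, 2)))


class TestTotalAccuracy:
    @pytest.mark.parametrize(
        "eta_p,eta_w,expected_pct",
        [(0.7741, 0.7127, 55.17), (0.7487, 0.7610, 56.98),
         (0.6498, 0.6475, 42.07)],
    )
    def test_benchmark_comparison_rows(self, eta_p, eta_w, expected_pct):
        assert round(100 * total_accuracy(eta_p, eta_w), 2) == expected_pct

    def test_zero_annihilates(self):
        assert total_accuracy(0.0, 0.73) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            total_accuracy(1.2, 0.5)
        with pytest.raises(ValueError):
            total_accuracy(0.5, -0.1)


class TestPerClassReport:
    def test_silent_class_gets_zeros(self):
        # class 1: nothing correct, nothing predicted as it
        mat = np.array([[5, 0], [3, 0]])
        rep = per_class_report(mat)
        row = rep.iloc[1]
        assert row["precision"] == 0.0 and row["recall"] == 0.0 \
            and row["f1"] == 0.0

    def test_f1_harmonic_mean(self):
        # precision 0.92, recall 1.00 -> F1 = 2*0.92/1.92
        mat = np.array([[23, 0], [2, 75]])
        rep = per_class_report(mat)
        assert rep.iloc[0]["precision"] == pytest.approx(0.92)
        assert rep.iloc[0]["recall"] == 1.0
        assert rep.iloc[0]["f1"] == pytest.approx(2 * 0.92 / 1.92)
        assert round(rep.iloc[0]["f1"], 2) == 0.96

    def test_matches_per_cell_tp_fp_fn_arithmetic(self, rng):
        mat = rng.integers(0, 12, size=(10, 10))
        rep = per_class_report(mat)
        for s in range(10):
            tp = mat[s, s]
            fp = mat[:, s].sum() - tp
            fn = mat[s, :].sum() - tp
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert rep.iloc[s]["precision"] == pytest.approx(prec)
            assert rep.iloc[s]["recall"] == pytest.approx(rec)
            assert rep.iloc[s]["f1"] == pytest.approx(f1)


class TestOracleEquivalence:
    """eta_p is micro accuracy, eta_w macro recall: check against sklearn."""

    def test_against_sklearn_on_random_predictions(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 12))
            n = int(rng.integers(20, 200))
            truth = rng.integers(0, k, size=n)
            pred = rng.integers(0, k, size=n)
            mat = confusion_matrix(truth, pred, k)
            assert patch_to_scan_accuracy(mat) == pytest.approx(
                accuracy_score(truth, pred), abs=1e-12)
            supported = np.flatnonzero(mat.sum(axis=1) > 0)
            _, rec, _, _ = precision_recall_fscore_support(
                truth, pred, labels=supported, zero_division=0)
            assert whole_scan_accuracy(mat) == pytest.approx(
                rec.mean(), abs=1e-12)


class TestProperties:
    def test_total_bounded_by_factors(self, rng):
        for _ in range(20):
            mat = rng.integers(0, 9, size=(5, 5)) + np.eye(5, dtype=int)
            ep = patch_to_scan_accuracy(mat)
            ew = whole_scan_accuracy(mat)
            et = total_accuracy(ep, ew)
            assert 0.0 <= et <= min(ep, ew) <= max(ep, ew) <= 1.0

    def test_class_permutation_invariance(self, rng):
        mat = rng.integers(1, 10, size=(6, 6))
        perm = rng.permutation(6)
        permuted = mat[np.ix_(perm, perm)]
        assert patch_to_scan_accuracy(mat) == pytest.approx(
            patch_to_scan_accuracy(permuted))
        assert whole_scan_accuracy(mat) == pytest.approx(
            whole_scan_accuracy(permuted))

    def test_adding_correct_patch_never_decreases_scores(self, rng):
        mat = rng.integers(0, 8, size=(4, 4)) + np.eye(4, dtype=int)
        ep, ew = patch_to_scan_accuracy(mat), whole_scan_accuracy(mat)
        for s in range(4):
            more = mat.copy()
            more[s, s] += 1
            assert patch_to_scan_accuracy(more) >= ep
            assert whole_scan_accuracy(more) >= ew


class TestReportsAndRenderers:
    def test_evaluation_report_consistency(self, rng):
        truth = rng.integers(0, 4, size=100)
        pred = rng.integers(0, 4, size=100)
        rep = EvaluationReport.from_predictions(truth, pred, 4)
        assert rep.eta_total == rep.eta_p * rep.eta_w  # unrounded product
        assert rep.confusion.sum(axis=1).tolist() == \
            np.bincount(truth, minlength=4).tolist()

    def test_prediction_set_retrieved_sets(self):
        ps = PredictionSet(predicted=[0, 1, 1, 0], truth=[0, 1, 0, 1],
                           num_classes=2)
        np.testing.assert_array_equal(ps.retrieved(1), [1, 2])

    def test_perfect_comparison_row(self):
        rep = EvaluationReport.from_confusion(np.diag([4, 4, 4]))
        table = comparison_table([("perfect", rep)])
        row = table.iloc[0]
        assert (row["eta_p_pct"], row["eta_w_pct"], row["eta_total_pct"]) \
            == (100.0, 100.0, 100.0)
        assert "100.00 100.00 100.00" in " ".join(
            render_comparison_table(table).split())

    def test_comparison_row_is_product_of_unrounded(self):
        rep = EvaluationReport(eta_p=0.7990, eta_w=0.7133,
                               eta_total=0.7990 * 0.7133,
                               confusion=np.eye(2, dtype=int),
                               per_class=per_class_report(np.eye(2, dtype=int)))
        table = comparison_table([("m", rep)])
        assert table.iloc[0]["eta_total_pct"] == round(
            100 * 0.7990 * 0.7133, 2)

    def test_duplicate_names_rejected(self):
        rep = EvaluationReport.from_confusion(np.diag([2, 2]))
        with pytest.raises(ValueError):
            comparison_table([("a", rep), ("a", rep)])

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            comparison_table([])

    def test_rendered_per_class_two_decimals(self):
        mat = np.array([[2, 1], [0, 3]])
        text = render_per_class_table(per_class_report(mat))
        assert "0.67" in text  # recall of class 0 = 2/3

    def test_confusion_csv_headers(self, tmp_path):
        path = tmp_path / "conf.csv"
        confusion_to_csv(np.diag([1, 2, 3]), path)
        header = path.read_text().splitlines()[0]
        assert header.endswith("c0,c1,c2")
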