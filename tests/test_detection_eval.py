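import math

import numpy as np
import pytest

from dermspec.detection_eval import (
    Detection,
    ExtendedConfusionMatrix,
    GroundTruth,
    class_metrics,
    f1_from_pr,
    giou,
    iou,
    match_and_count,
    read_detections_csv,
    read_ground_truth_csv,
    write_detections_csv,
    write_ground_truth_csv,
)
from dermspec.errors import DermspecError
from dermspec.fixtures import detections_from_matrix

LABELS = ["BCC", "SCC", "SK"]


class TestIou:
    def test_identical(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint(self):
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_arithmetic(self):
        assert iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_symmetry(self):
        rng = np.random.default_rng(51)
        for _ in range(20):
            x = rng.uniform(0, 10, 4)
            a = (min(x[0], x[1]), min(x[2], x[3]), max(x[0], x[1]) + 1, max(x[2], x[3]) + 1)
            y = rng.uniform(0, 10, 4)
            b = (min(y[0], y[1]), min(y[2], y[3]), max(y[0], y[1]) + 1, max(y[2], y[3]) + 1)
            assert iou(a, b) == pytest.approx(iou(b, a))
            assert 0 <= iou(a, b) <= 1


class TestGiou:
    def test_identical(self):
        assert giou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint_arithmetic(self):
        assert giou((0, 0, 1, 1), (2, 0, 3, 1)) == pytest.approx(-1 / 3)

    def test_never_exceeds_iou(self):
        rng = np.random.default_rng(52)
        for _ in range(50):
            x = rng.uniform(0, 10, 4)
            a = (min(x[0], x[1]), min(x[2], x[3]), max(x[0], x[1]) + 0.5, max(x[2], x[3]) + 0.5)
            y = rng.uniform(0, 10, 4)
            b = (min(y[0], y[1]), min(y[2], y[3]), max(y[0], y[1]) + 0.5, max(y[2], y[3]) + 0.5)
            assert giou(a, b) <= iou(a, b) + 1e-12
            assert -1 < giou(a, b) <= 1


class TestMatrixType:
    def test_background_background_must_be_zero(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[3, 3] = 1
        with pytest.raises(DermspecError):
            ExtendedConfusionMatrix(counts, LABELS)

    def test_negative_rejected(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = -1
        with pytest.raises(DermspecError):
            ExtendedConfusionMatrix(counts, LABELS)

    def test_shape_checked(self):
        with pytest.raises(DermspecError):
            ExtendedConfusionMatrix(np.zeros((3, 3), dtype=int), LABELS)

    def test_published_matrix_totals(self, rgb_matrix, hsi_matrix):
        assert rgb_matrix.correct_count == 301
        assert hsi_matrix.correct_count == 274
        assert rgb_matrix.true_class_totals().tolist() == [168, 90, 126]
        assert hsi_matrix.true_class_totals().tolist() == [168, 90, 126]


class TestMatchAndCount:
    def test_perfect_detections_diagonal(self):
        gts, dets = [], []
        for i, cls in enumerate(range(3)):
            box = (i * 50.0, 0.0, i * 50.0 + 40, 40.0)
            gts.append(GroundTruth("a", cls, box))
            dets.append(Detection("a", cls, 0.9, box))
        m = match_and_count(dets, gts, LABELS)
        assert np.array_equal(m.counts[:3, :3], np.eye(3, dtype=int))
        assert m.counts[3].sum() == 0 and m.counts[:, 3].sum() == 0

    def test_no_detections_all_background_fn(self):
        gts = [GroundTruth("a", 1, (0, 0, 10, 10)), GroundTruth("a", 2, (20, 20, 30, 30))]
        m = match_and_count([], gts, LABELS)
        assert m.counts[3, 1] == 1 and m.counts[3, 2] == 1
        assert m.counts.sum() == 2

    def test_low_confidence_discarded(self):
        box = (0.0, 0.0, 10.0, 10.0)
        m = match_and_count(
            [Detection("a", 0, 0.1, box)], [GroundTruth("a", 0, box)], LABELS
        )
        assert m.counts[0, 0] == 0
        assert m.counts[3, 0] == 1

    def test_highest_iou_preferred(self):
        det = Detection("a", 0, 0.9, (0.0, 0.0, 10.0, 10.0))
        gt_close = GroundTruth("a", 1, (1.0, 0.0, 11.0, 10.0))
        gt_far = GroundTruth("a", 2, (4.0, 0.0, 14.0, 10.0))
        m = match_and_count([det], [gt_far, gt_close], LABELS, iou_threshold=0.3)
        assert m.counts[0, 1] == 1  # matched the closer one
        assert m.counts[3, 2] == 1

    def test_confidence_order_greedy(self):
        box = (0.0, 0.0, 10.0, 10.0)
        dets = [
            Detection("a", 0, 0.6, box),
            Detection("a", 1, 0.95, box),
        ]
        m = match_and_count(dets, [GroundTruth("a", 2, box)], LABELS)
        # higher-confidence detection takes the ground truth
        assert m.counts[1, 2] == 1
        assert m.counts[0, 3] == 1

    def test_images_are_independent(self):
        box = (0.0, 0.0, 10.0, 10.0)
        m = match_and_count(
            [Detection("a", 0, 0.9, box)], [GroundTruth("b", 0, box)], LABELS
        )
        assert m.counts[0, 3] == 1 and m.counts[3, 0] == 1

    def test_conservation(self):
        rng = np.random.default_rng(53)
        dets, gts = [], []
        for i in range(60):
            x, y = rng.uniform(0, 500, 2)
            gts.append(GroundTruth(f"im{i % 7}", int(rng.integers(3)), (x, y, x + 20, y + 20)))
            if rng.random() < 0.8:
                dx, dy = rng.uniform(-5, 5, 2)
                dets.append(
                    Detection(
                        f"im{i % 7}", int(rng.integers(3)), float(rng.uniform(0.3, 1)),
                        (x + dx, y + dy, x + dx + 20, y + dy + 20),
                    )
                )
        m = match_and_count(dets, gts, LABELS)
        for c in range(3):
            n_gt = sum(1 for g in gts if g.class_index == c)
            assert m.counts[:, c].sum() == n_gt
            n_det = sum(1 for d in dets if d.class_index == c and d.confidence >= 0.25)
            assert m.counts[c, :].sum() == n_det

    def test_raising_confidence_never_increases_lesion_rows(self):
        rng = np.random.default_rng(54)
        dets, gts = [], []
        for i in range(40):
            x, y = rng.uniform(0, 300, 2)
            gts.append(GroundTruth("a", int(rng.integers(3)), (x, y, x + 15, y + 15)))
            dets.append(
                Detection("a", int(rng.integers(3)), float(rng.uniform(0, 1)),
                          (x + 1, y + 1, x + 16, y + 16))
            )
        previous = None
        for conf in (0.1, 0.3, 0.5, 0.7, 0.9):
            m = match_and_count(dets, gts, LABELS, confidence_threshold=conf)
            rows = m.counts[:3, :]
            if previous is not None:
                assert np.all(rows.sum(axis=1) <= previous.sum(axis=1))
            previous = rows

    def test_bad_class_index_rejected(self):
        with pytest.raises(DermspecError):
            match_and_count([Detection("a", 7, 0.9, (0, 0, 1, 1))], [], LABELS)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(DermspecError):
            match_and_count([], [], LABELS, iou_threshold=0.0)


class TestRoundTrip:
    def test_published_matrices_round_trip(self, rgb_matrix, hsi_matrix):
        for matrix in (rgb_matrix, hsi_matrix):
            dets, gts = detections_from_matrix(matrix, geometry_seed=3)
            recovered = match_and_count(dets, gts, LABELS)
            assert np.array_equal(recovered.counts, matrix.counts)

    def test_random_matrices_round_trip(self):
        rng = np.random.default_rng(55)
        for _ in range(25):
            counts = rng.integers(0, 30, (4, 4))
            counts[3, 3] = 0
            matrix = ExtendedConfusionMatrix(counts, LABELS)
            dets, gts = detections_from_matrix(matrix, geometry_seed=int(rng.integers(1000)))
            recovered = match_and_count(dets, gts, LABELS)
            assert np.array_equal(recovered.counts, counts)


class TestClassMetrics:
    def test_identity_matrix_all_ones(self):
        counts = np.zeros((4, 4), dtype=int)
        np.fill_diagonal(counts[:3, :3], 10)
        table = class_metrics(ExtendedConfusionMatrix(counts, LABELS))
        for m in table.per_class.values():
            assert m.precision == m.recall == m.specificity == m.f1 == 1.0
        assert table.accuracy == 1.0

    def test_published_correct_counts(self, rgb_matrix, hsi_matrix):
        assert class_metrics(rgb_matrix).correct_count == 301
        assert class_metrics(hsi_matrix).correct_count == 274

    def test_published_bcc_precision_exclude_background(self, rgb_matrix):
        table = class_metrics(rgb_matrix, "exclude-background")
        assert round(table.per_class["BCC"].precision, 3) == 0.899  # 133/148

    def test_include_background_convention(self, rgb_matrix):
        table = class_metrics(rgb_matrix, "include-background")
        assert table.per_class["BCC"].precision == pytest.approx(133 / 193)

    def test_accuracy_over_true_columns(self, rgb_matrix):
        table = class_metrics(rgb_matrix)
        assert table.accuracy == pytest.approx(301 / 384)

    def test_zero_denominator_is_nan(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[3, 0] = 5  # only missed BCC ground truths
        table = class_metrics(ExtendedConfusionMatrix(counts, LABELS))
        assert math.isnan(table.per_class["BCC"].precision)
        assert table.per_class["BCC"].recall == 0.0

    def test_unknown_convention_rejected(self, rgb_matrix):
        with pytest.raises(DermspecError):
            class_metrics(rgb_matrix, "both")

    def test_correct_count_is_lesion_trace(self):
        rng = np.random.default_rng(56)
        counts = rng.integers(0, 20, (4, 4))
        counts[3, 3] = 0
        matrix = ExtendedConfusionMatrix(counts, LABELS)
        assert matrix.correct_count == counts[0, 0] + counts[1, 1] + counts[2, 2]


class TestF1:
    def test_perfect(self):
        assert f1_from_pr(1.0, 1.0) == 1.0

    def test_published_rgb_bcc(self):
        assert round(f1_from_pr(0.899, 0.747), 3) == 0.816

    def test_published_hsi_scc(self):
        assert round(f1_from_pr(0.746, 0.794), 3) == 0.769

    def test_zero_sum_undefined(self):
        assert math.isnan(f1_from_pr(0.0, 0.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(DermspecError):
            f1_from_pr(1.2, 0.5)


class TestIo:
    def test_detection_csv_round_trip(self, tmp_path):
        dets = [
            Detection("im1", 0, 0.75, (1.0, 2.0, 3.0, 4.0)),
            Detection("im2", 2, 0.5, (10.0, 10.0, 20.0, 20.0)),
        ]
        path = tmp_path / "dets.csv"
        write_detections_csv(dets, path)
        assert read_detections_csv(path) == dets

    def test_ground_truth_csv_round_trip(self, tmp_path):
        gts = [GroundTruth("im1", 1, (0.0, 0.0, 5.0, 5.0))]
        path = tmp_path / "gts.csv"
        write_ground_truth_csv(gts, path)
        assert read_ground_truth_csv(path) == gts

    def test_matrix_text_layout(self, rgb_matrix):
        text = rgb_matrix.to_text()
        assert "Background FN" in text and "Background FP" in text
        assert "133" in text
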