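"""Watershed pipeline, IoU matching, AP, and the threshold sweep."""

import numpy as np
import pytest

from spotlight3d import (
    ValidationError,
    average_precision,
    iou_matrix,
    match_instances,
    threshold_sweep,
    watershed_segment,
)
from spotlight3d.segmentation import relabel_consecutive, segment_with


def paint_sphere(shape, center, radius, value=1.0):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    vol = np.zeros(shape)
    vol[d2 <= radius**2] = value
    return vol


class TestWatershed:
    def test_constant_volume_gives_empty_labels_with_warning(self):
        with pytest.warns(UserWarning):
            labels = watershed_segment(np.zeros((8, 8, 8)))
        assert labels.max() == 0

    def test_single_sphere_single_instance(self):
        vol = paint_sphere((24, 24, 24), (12, 12, 12), 6)
        labels = watershed_segment(vol)
        assert labels.max() == 1
        gt = (vol > 0).astype(int)
        inter = ((labels == 1) & (gt == 1)).sum()
        union = ((labels == 1) | (gt == 1)).sum()
        assert inter / union >= 0.8

    def test_two_separated_spheres_two_instances(self):
        vol = paint_sphere((24, 40, 24), (12, 10, 12), 5)
        vol += paint_sphere((24, 40, 24), (12, 30, 12), 5)
        labels = watershed_segment(vol)
        assert labels.max() == 2

    def test_small_objects_removed(self):
        vol = paint_sphere((24, 24, 24), (12, 12, 12), 6)
        vol[0, 0, 0] = 1.0  # single-voxel speck
        labels = watershed_segment(vol, min_object_voxels=27)
        assert labels.max() == 1

    def test_correct_count_on_many_seeded_fixtures(self):
        """Sharp FG/BG fixtures: the pipeline finds the planted count >= 95%."""
        from spotlight3d import SynthConfig, generate_sample, normalize_volume

        hits = 0
        n = 50
        for seed in range(200, 200 + n):
            s = generate_sample(
                SynthConfig(shape=(40, 40, 40), n_nuclei=3, radius_range=(3.5, 5.0),
                            axial_elongation_sigma=(1.5, 0.8, 0.8), seed=seed)
            )
            clean, _ = normalize_volume(s.clean_volume)
            labels = watershed_segment(clean)
            hits += int(labels.max() == s.n_placed)
        assert hits / n >= 0.95


class TestIoUMatrix:
    def test_identical_labelings_have_unit_diagonal(self, small_sample):
        res = iou_matrix(small_sample.labels, small_sample.labels)
        np.testing.assert_allclose(np.diag(res.iou), 1.0)

    def test_disjoint_instances_all_zero(self):
        a = np.zeros((4, 4, 4), dtype=int)
        b = np.zeros((4, 4, 4), dtype=int)
        a[0], b[3] = 1, 1
        assert iou_matrix(a, b).iou.max() == 0.0

    def test_hand_counted_overlap(self):
        # gt: 100 voxels; pred covers 60 of them plus 40 background voxels:
        # IoU = 60 / (100 + 100 - 60) = 60/140 = 3/7
        gt = np.zeros((5, 5, 8), dtype=int)
        gt.ravel()[:100] = 1
        pred = np.zeros_like(gt)
        pred.ravel()[40:140] = 1
        res = iou_matrix(gt, pred)
        assert res.iou[0, 0] == pytest.approx(60 / 140, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            iou_matrix(np.zeros((2, 2, 2), int), np.zeros((2, 2, 3), int))


class TestAveragePrecision:
    def _two_gt_one_pred(self):
        gt = np.zeros((6, 6, 12), dtype=int)
        gt[:, :, :4] = 1
        gt[:, :, 8:] = 2
        pred = np.zeros_like(gt)
        # gt1 has 144 voxels; pred covers 108 of them plus 36 background
        # voxels -> IoU = 108 / (144 + 144 - 108) = 0.6
        pred[:, :, :3] = 1
        pred[:3, :4, 5:8] = 1
        return gt, pred

    def test_perfect_prediction_scores_one_everywhere(self, small_sample):
        rep = average_precision(small_sample.labels, small_sample.labels)
        np.testing.assert_allclose(rep.ap, 1.0)

    def test_empty_prediction_scores_zero(self, small_sample):
        rep = average_precision(small_sample.labels, np.zeros_like(small_sample.labels))
        np.testing.assert_allclose(rep.ap, 0.0)

    def test_two_gt_one_pred_at_two_thresholds(self):
        gt, pred = self._two_gt_one_pred()
        iou = iou_matrix(gt, pred).iou
        assert iou[0, 0] == pytest.approx(0.6, abs=1e-12)
        rep = average_precision(gt, pred, iou_thresholds=(0.5, 0.75))
        # @0.5: TP=1, FP=0, FN=1 -> 0.5 ; @0.75: TP=0, FP=1, FN=2 -> 0.0
        assert rep.ap[0] == pytest.approx(0.5)
        assert rep.ap[1] == pytest.approx(0.0)

    def test_ap_antitone_in_iou_threshold(self):
        rng = np.random.default_rng(77)
        grid = (0.3, 0.5, 0.7, 0.9)
        for _ in range(20):
            gt = rng.integers(0, 4, size=(8, 8, 8))
            pred = gt.copy()
            flip = rng.uniform(size=gt.shape) < 0.2
            pred[flip] = rng.integers(0, 4, size=int(flip.sum()))
            rep = average_precision(gt, pred, iou_thresholds=grid)
            assert np.all(np.diff(rep.ap) <= 1e-12)

    def test_swapping_gt_and_pred_swaps_fp_fn(self, small_sample):
        pred = np.roll(small_sample.labels, 2, axis=0)
        a = match_instances(iou_matrix(small_sample.labels, pred), 0.5)
        b = match_instances(iou_matrix(pred, small_sample.labels), 0.5)
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fn, b.fp)

    def test_greedy_equals_optimal_on_fixtures(self, small_sample):
        fixtures = [
            (small_sample.labels, np.roll(small_sample.labels, 1, axis=1)),
            self._two_gt_one_pred(),
            (small_sample.labels, small_sample.labels),
        ]
        rng = np.random.default_rng(5)
        noisy = small_sample.labels.copy()
        noisy[rng.uniform(size=noisy.shape) < 0.1] = 0
        fixtures.append((small_sample.labels, noisy))
        for gt, pred in fixtures:
            for thr in (0.3, 0.5, 0.75):
                g = match_instances(iou_matrix(gt, pred), thr, method="greedy")
                o = match_instances(iou_matrix(gt, pred), thr, method="optimal")
                assert g.tp == o.tp

    def test_both_empty_is_perfect(self):
        z = np.zeros((4, 4, 4), dtype=int)
        rep = average_precision(z, z)
        np.testing.assert_allclose(rep.ap, 1.0)


class TestThresholdSweep:
    def test_below_minimum_matches_unthresholded(self, small_sample):
        from spotlight3d import normalize_volume

        tgt, _ = normalize_volume(small_sample.target_volume)
        tab = threshold_sweep(tgt, small_sample.labels, thresholds=[-1.0])
        direct = average_precision(
            small_sample.labels, watershed_segment(tgt), iou_thresholds=(0.5,)
        )
        assert tab["AP"].iloc[0] == pytest.approx(direct.ap[0])

    def test_above_maximum_removes_everything(self, small_sample):
        from spotlight3d import normalize_volume

        tgt, _ = normalize_volume(small_sample.target_volume)
        with pytest.warns(UserWarning):
            tab = threshold_sweep(tgt, small_sample.labels, thresholds=[2.0])
        assert tab["AP"].iloc[0] == 0.0
        assert tab["n_instances"].iloc[0] == 0

    def test_rows_match_standalone_calls(self, small_sample):
        from spotlight3d import normalize_volume

        tgt, _ = normalize_volume(small_sample.target_volume)
        ts = [0.1, 0.3]
        tab = threshold_sweep(tgt, small_sample.labels, thresholds=ts)
        for t, row_ap in zip(ts, tab["AP"]):
            cut = np.where(tgt >= t, tgt, 0.0)
            rep = average_precision(
                small_sample.labels, watershed_segment(cut), iou_thresholds=(0.5,)
            )
            assert row_ap == pytest.approx(rep.ap[0])


def test_relabel_consecutive_preserves_partition():
    labels = np.array([[[0, 5], [5, 9]]])
    out = relabel_consecutive(labels)
    np.testing.assert_array_equal(out, [[[0, 1], [1, 2]]])


def test_segment_with_adapter_normalizes_labels(small_sample):
    out = segment_with(lambda v: (v > v.mean()).astype(int) * 7, small_sample.target_volume)
    assert set(np.unique(out)) <= {0, 1}
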