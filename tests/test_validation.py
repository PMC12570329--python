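"""Pixel- and object-level validation metrics against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import spinemorph as sm

from conftest import SPACING, random_blob_labels, random_mask


def oracle_dice(a, b):
    sa, sb = a.sum(), b.sum()
    return 1.0 if sa + sb == 0 else 2.0 * (a & b).sum() / (sa + sb)


def oracle_iou(a, b):
    u = (a | b).sum()
    return 1.0 if u == 0 else (a & b).sum() / u


def oracle_hausdorff(a, b, spacing):
    """All-pairs max-min over surface voxels (6-connectivity surface)."""

    def surface(mask):
        out = []
        for v in np.argwhere(mask):
            for ax in range(3):
                for d in (-1, 1):
                    n = v.copy()
                    n[ax] += d
                    if np.any(n < 0) or np.any(n >= mask.shape) or not mask[tuple(n)]:
                        out.append(v)
                        break
                else:
                    continue
                break
        return np.array(out) * np.asarray(spacing)

    sa, sb = surface(a), surface(b)
    d_ab = max(min(np.linalg.norm(p - q) for q in sb) for p in sa)
    d_ba = max(min(np.linalg.norm(p - q) for q in sa) for p in sb)
    return max(d_ab, d_ba)


class TestPixelMetrics:
    def test_identical_masks_score_one(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[1:3, 1:3, 1:3] = True
        assert sm.dice(a, a) == 1.0
        assert sm.iou(a, a) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert sm.dice(a, b) == 0.0
        assert sm.iou(a, b) == 0.0

    def test_both_empty_score_one_by_convention(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        assert sm.dice(a, a.copy()) == 1.0
        assert sm.iou(a, a.copy()) == 1.0

    def test_exactly_one_empty_scores_zero(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        b = a.copy()
        b[1, 1, 1] = True
        assert sm.dice(a, b) == 0.0

    def test_shifted_cube_hand_computed_overlap(self):
        # 2x2x2 cube vs itself shifted one voxel in x: overlap 4 of 8
        a = np.zeros((4, 4, 5), dtype=bool)
        a[1:3, 1:3, 1:3] = True
        b = np.roll(a, 1, axis=2)
        assert sm.dice(a, b) == pytest.approx(0.5)
        assert sm.iou(a, b) == pytest.approx(1 / 3)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="congruent"):
            sm.dice(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 4), bool))

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_equivalence_and_dice_iou_identity(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 9, size=3))
        a = random_mask(rng, shape, 0.4)
        b = random_mask(rng, shape, 0.4)
        d, j = sm.dice(a, b), sm.iou(a, b)
        assert d == pytest.approx(oracle_dice(a, b), abs=1e-12)
        assert j == pytest.approx(oracle_iou(a, b), abs=1e-12)
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)


class TestMatching:
    def test_identical_instance_maps_all_matched(self):
        rng = np.random.default_rng(0)
        lab = random_blob_labels(rng, (8, 8, 8), n_seeds=5)
        k = len(np.unique(lab)) - 1
        for thr in (0.1, 0.5, 0.9):
            counts, _ = sm.match_objects(lab, lab, thr)
            assert (counts.tp, counts.fp, counts.fn) == (k, 0, 0)

    def test_overlap_below_threshold_counts_fp_and_fn(self):
        gt = np.zeros((4, 5, 5), dtype=int)
        gt[1:3, 1:4, 1:4] = 1  # 18 voxels
        pred = np.zeros_like(gt)
        pred[1:3, 1:4, 1:3] = 1  # 12 voxels, all inside gt -> IoU 12/18 = 0.667
        counts, _ = sm.match_objects(pred, gt, 0.7)
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)
        counts, _ = sm.match_objects(pred, gt, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_counts_match_optimal_assignment_oracle(self, seed):
        # where row/column maxima are unique the greedy matching is optimal
        rng = np.random.default_rng(100 + seed)
        pred = random_blob_labels(rng, (8, 8, 8), n_seeds=int(rng.integers(1, 6)))
        gt = random_blob_labels(rng, (8, 8, 8), n_seeds=int(rng.integers(1, 6)))
        thr = 0.5
        pred_ids, gt_ids, mat = sm.pairwise_iou(pred, gt)
        counts, _ = sm.match_objects(pred, gt, thr)
        if mat.size:
            cost = np.where(mat >= thr, -mat, 0.0)
            ri, ci = linear_sum_assignment(cost)
            tp_opt = int(sum(mat[r, c] >= thr for r, c in zip(ri, ci)))
        else:
            tp_opt = 0
        assert counts.tp == tp_opt
        assert counts.tp + counts.fp == len(pred_ids)
        assert counts.tp + counts.fn == len(gt_ids)

    def test_matching_invariant_under_relabelling(self):
        rng = np.random.default_rng(4)
        pred = random_blob_labels(rng, (8, 8, 8), n_seeds=4)
        gt = random_blob_labels(rng, (8, 8, 8), n_seeds=4)
        perm = {0: 0}
        for i in np.unique(pred):
            if i > 0:
                perm[int(i)] = int(i) + 17
        pred2 = np.vectorize(perm.get)(pred)
        c1, _ = sm.match_objects(pred, gt, 0.3)
        c2, _ = sm.match_objects(pred2, gt, 0.3)
        assert (c1.tp, c1.fp, c1.fn) == (c2.tp, c2.fp, c2.fn)


class TestScores:
    def test_reported_precision_recall_combination(self):
        # precision 0.988 with recall 0.9 yields an F1 that rounds to 0.94
        counts = sm.MatchCounts(tp=900, fp=11, fn=100, iou_threshold=0.5)
        p, r, f1 = sm.precision_recall_f1(counts)
        assert p == pytest.approx(0.988, abs=5e-4)
        assert r == pytest.approx(0.9, abs=1e-12)
        assert round(f1, 2) == 0.94

    def test_direct_arithmetic(self):
        p, r, f1 = sm.precision_recall_f1(sm.MatchCounts(3, 1, 1, 0.5))
        assert (p, r, f1) == (0.75, 0.75, 0.75)

    def test_all_zero_counts_are_undefined(self):
        p, r, f1 = sm.precision_recall_f1(sm.MatchCounts(0, 0, 0, 0.5))
        assert p is None and r is None and f1 is None

    def test_zero_tp_with_detections_gives_zero_f1(self):
        p, r, f1 = sm.precision_recall_f1(sm.MatchCounts(0, 2, 3, 0.5))
        assert (p, r, f1) == (0.0, 0.0, 0.0)


class TestF1Curve:
    def test_perfect_prediction_scores_one_everywhere(self):
        rng = np.random.default_rng(1)
        lab = random_blob_labels(rng, (8, 8, 8), n_seeds=4)
        curve = sm.f1_curve(lab, lab)
        assert len(curve) == 9
        assert all(f == 1.0 for _, f in curve)

    def test_single_pair_with_iou_055_is_a_step_function(self):
        gt = np.zeros((3, 5, 5), dtype=int)
        gt[1, 1:4, 1:4] = 1  # 9 voxels
        pred = np.zeros_like(gt)
        pred[1, 1:4, 1:3] = 1
        pred[1, 1, 3] = 1  # overlap 7, union 11 -> IoU 0.636
        ratio = sm.iou(pred > 0, gt > 0)
        curve = dict(sm.f1_curve(pred, gt))
        for thr, f in curve.items():
            assert f == (1.0 if thr <= ratio else 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_non_increasing_on_random_fixtures(self, seed):
        rng = np.random.default_rng(200 + seed)
        pred = random_blob_labels(rng, (10, 10, 10), n_seeds=5)
        gt = random_blob_labels(rng, (10, 10, 10), n_seeds=5)
        curve = [f for _, f in sm.f1_curve(pred, gt)]
        vals = [f for f in curve if f is not None]
        assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))


class TestHausdorff:
    def test_identical_masks_distance_zero(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[1:3, 1:3, 1:3] = True
        assert sm.hausdorff(a, a, SPACING) == 0.0

    def test_two_voxels_three_lateral_steps_apart(self):
        a = np.zeros((3, 3, 6), dtype=bool)
        b = np.zeros((3, 3, 6), dtype=bool)
        a[1, 1, 1] = True
        b[1, 1, 4] = True
        assert sm.hausdorff(a, b, SPACING) == pytest.approx(0.195)

    def test_empty_mask_rejected(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        b = a.copy()
        b[1, 1, 1] = True
        with pytest.raises(ValueError):
            sm.hausdorff(a, b, SPACING)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle_on_random_blobs(self, seed):
        rng = np.random.default_rng(300 + seed)
        shape = tuple(rng.integers(3, 8, size=3))
        a = random_mask(rng, shape, 0.35)
        b = random_mask(rng, shape, 0.35)
        if not a.any() or not b.any():
            pytest.skip("degenerate draw")
        assert sm.hausdorff(a, b, SPACING) == pytest.approx(
            oracle_hausdorff(a, b, SPACING), abs=1e-9
        )

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(9)
        masks = []
        while len(masks) < 3:
            m = random_mask(rng, (5, 6, 6), 0.3)
            if m.any():
                masks.append(m)
        a, b, c = masks
        dab = sm.hausdorff(a, b, SPACING)
        dba = sm.hausdorff(b, a, SPACING)
        dac = sm.hausdorff(a, c, SPACING)
        dcb = sm.hausdorff(c, b, SPACING)
        assert dab == dba
        assert dab <= dac + dcb + 1e-9

    def test_hd95_not_larger_than_full_maximum(self):
        rng = np.random.default_rng(13)
        a = random_mask(rng, (6, 8, 8), 0.3)
        b = random_mask(rng, (6, 8, 8), 0.3)
        assert sm.hausdorff(a, b, SPACING, percentile=95) <= sm.hausdorff(a, b, SPACING)


class TestReport:
    def test_full_report_shapes_and_f1_consistency(self, straight_scene):
        _, v, m, inst, gt = straight_scene
        pred_labels = np.roll(m.labels, 1, axis=2)  # slightly degraded prediction
        pred_inst = np.roll(inst, 1, axis=2)
        report = sm.validate_label_maps(
            pred_labels, m.labels, pred_inst, inst, SPACING, sm.CLASS_CODES
        )
        assert set(report.dice_per_class) == {"dendrite", "soma", "spine_head", "spine_neck"}
        for thr, f1 in report.f1.items():
            p, r = report.precision[thr], report.recall[thr]
            if None not in (p, r) and p + r > 0:
                assert f1 == pytest.approx(2 * p * r / (p + r))
        assert all(d >= 0 for d in report.hausdorff_um.values())
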