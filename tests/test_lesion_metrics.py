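import numpy as np
import pytest

from msunet.lesion_metrics import (DEFAULT_SIZE_BINS, cohort_correlations,
                                   detection_metrics, evaluate_scan,
                                   find_lesions, segmentation_metrics,
                                   size_stratified, structure_18)
from msunet.volume_io import LesionMask, VolumeGrid

GRID16 = VolumeGrid((16, 16, 16), (3.0, 1.0, 1.0))


def mask_of(arr, grid=GRID16):
    full = np.zeros(grid.shape, dtype=np.uint8)
    full[tuple(slice(0, s) for s in np.shape(arr))] = arr
    return LesionMask(grid, full)


# -- independent oracles ----------------------------------------------------

def stencil_18():
    """Explicitly enumerated 18-neighbour offsets (faces + edges)."""
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                n_nonzero = (dz != 0) + (dy != 0) + (dx != 0)
                if 1 <= n_nonzero <= 2:
                    offs.append((dz, dy, dx))
    return offs


def flood_fill_components(labels, min_size=3):
    """BFS flood fill with the enumerated 18-stencil."""
    offs = stencil_18()
    seen = np.zeros_like(labels, dtype=bool)
    comps = []
    shape = labels.shape
    for start in np.argwhere(labels):
        start = tuple(start)
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            v = queue.pop()
            comp.append(v)
            for dz, dy, dx in offs:
                n = (v[0] + dz, v[1] + dy, v[2] + dx)
                if (0 <= n[0] < shape[0] and 0 <= n[1] < shape[1]
                        and 0 <= n[2] < shape[2]
                        and labels[n] and not seen[n]):
                    seen[n] = True
                    queue.append(n)
        if len(comp) >= min_size:
            comps.append(frozenset(comp))
    return set(comps)


def brute_force_detection(gt_comps, pred_comps, gt_bool, pred_bool, thr=0.1):
    """Iterate all (lesion, mask) overlap fractions explicitly."""
    det = sum(1 for c in gt_comps
              if sum(pred_bool[v] for v in c) / len(c) >= thr)
    fp = sum(1 for c in pred_comps
             if sum(gt_bool[v] for v in c) / len(c) < thr)
    ltpr = det / len(gt_comps) if gt_comps else float("nan")
    lfpr = fp / len(pred_comps) if pred_comps else float("nan")
    return ltpr, lfpr


# -- tests ------------------------------------------------------------------

class TestFindLesions:
    def test_corner_touching_voxels_are_separate(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        # two 2x2x1 plates sharing only the cube corner at (1,1,1)/(2,2,2)
        a[0:2, 0:2, 0:2] = 1
        a[2:4, 2:4, 2:4] = 1
        comps = find_lesions(mask_of(a), min_size=3)
        assert len(comps) == 2

    def test_edge_touching_voxels_connect(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0, 0, 0:2] = 1
        a[1, 1, 0:2] = 1  # shares an edge with the first pair
        comps = find_lesions(mask_of(a), min_size=3)
        assert len(comps) == 1
        assert comps[0].size_voxels == 4

    def test_two_voxel_blob_removed(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        a[1, 1, 1:3] = 1
        assert find_lesions(mask_of(a)) == []

    def test_volume_in_uL(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        a[1, 1, 0:4] = 1
        a[1, 2, 0:4] = 1
        a[1, 3, 0:2] = 1
        comps = find_lesions(mask_of(a))
        assert comps[0].size_voxels == 10
        assert comps[0].volume_uL == pytest.approx(30.0)

    def test_matches_flood_fill_oracle_random_masks(self, rng):
        for _ in range(50):
            labels = (rng.random((16, 16, 16)) < 0.08).astype(np.uint8)
            mask = LesionMask(GRID16, labels)
            comps = {frozenset(map(tuple, c.voxels))
                     for c in find_lesions(mask)}
            assert comps == flood_fill_components(labels)

    def test_structure_has_19_elements(self):
        # centre + 6 faces + 12 edges
        assert structure_18().sum() == 19


class TestSegmentationMetrics:
    def test_identical_masks(self, blob_mask):
        dc, ppv, tpr = segmentation_metrics(blob_mask, blob_mask)
        assert (dc, ppv, tpr) == (1.0, 1.0, 1.0)

    def test_superset_prediction_hand_count(self):
        gt = np.zeros((4, 4, 4), dtype=np.uint8)
        gt[0, 0:2, 0:5] = 0
        gt[0, 0, 0:4] = 1
        gt[0, 1, 0:1] = 1  # 5 voxels GT
        pred = gt.copy()
        pred[3, 3, 0:4] = 1  # plus 5 disjoint FP voxels
        pred[3, 2, 0] = 1
        dc, ppv, tpr = segmentation_metrics(mask_of(gt), mask_of(pred))
        assert tpr == 1.0
        assert ppv == pytest.approx(0.5)
        assert dc == pytest.approx(2 * 5 / (2 * 5 + 5 + 0))

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        dc, ppv, tpr = segmentation_metrics(mask_of(a), mask_of(b))
        assert (dc, ppv, tpr) == (0.0, 0.0, 0.0)

    def test_empty_vs_empty_convention(self):
        z = mask_of(np.zeros((4, 4, 4), dtype=np.uint8))
        assert segmentation_metrics(z, z) == (1.0, 1.0, 1.0)

    def test_empty_prediction_flags_ppv(self, blob_mask):
        empty = LesionMask(blob_mask.grid,
                           np.zeros(blob_mask.grid.shape, dtype=np.uint8))
        dc, ppv, tpr = segmentation_metrics(blob_mask, empty)
        assert np.isnan(ppv)
        assert tpr == 0.0

    def test_symmetry_of_dice(self, rng):
        a = (rng.random((16, 16, 16)) < 0.2).astype(np.uint8)
        b = (rng.random((16, 16, 16)) < 0.2).astype(np.uint8)
        dca, _, _ = segmentation_metrics(mask_of(a), mask_of(b))
        dcb, _, _ = segmentation_metrics(mask_of(b), mask_of(a))
        assert dca == pytest.approx(dcb)


class TestDetectionMetrics:
    def test_ten_percent_boundary_detected(self):
        gt = np.zeros((16, 16, 16), dtype=np.uint8)
        gt[2, 2, 2:12] = 1  # 10-voxel line lesion
        pred = np.zeros_like(gt)
        pred[2, 2, 2] = 1   # exactly 1 voxel = 10% overlap (>= rule)
        gm, pm = mask_of(gt), mask_of(pred)
        gl = find_lesions(gm)
        ltpr, lppv, lfpr = detection_metrics(gl, [], gm, pm)
        assert ltpr == 1.0

    def test_spurious_prediction_hand_count(self):
        gt = np.zeros((16, 16, 16), dtype=np.uint8)
        gt[2, 2:5, 2:5] = 1
        pred = gt.copy()
        pred[10, 10:13, 10:13] = 1  # one spurious lesion
        gm, pm = mask_of(gt), mask_of(pred)
        ltpr, lppv, lfpr = detection_metrics(
            find_lesions(gm), find_lesions(pm), gm, pm)
        assert ltpr == 1.0
        assert lfpr == pytest.approx(0.5)
        assert lppv == pytest.approx(0.5)

    def test_undefined_rates_flagged(self):
        empty = mask_of(np.zeros((4, 4, 4), dtype=np.uint8))
        ltpr, lppv, lfpr = detection_metrics([], [], empty, empty)
        assert np.isnan(ltpr) and np.isnan(lppv) and np.isnan(lfpr)

    def test_matches_brute_force_matcher(self, rng):
        for _ in range(100):
            gt = (rng.random((16, 16, 16)) < 0.06).astype(np.uint8)
            pred = (rng.random((16, 16, 16)) < 0.06).astype(np.uint8)
            gm, pm = mask_of(gt), mask_of(pred)
            gl, pl = find_lesions(gm), find_lesions(pm)
            ltpr, _, lfpr = detection_metrics(gl, pl, gm, pm)
            gt_comps = [set(map(tuple, c.voxels)) for c in gl]
            pr_comps = [set(map(tuple, c.voxels)) for c in pl]
            ref_ltpr, ref_lfpr = brute_force_detection(
                gt_comps, pr_comps, gt.astype(bool), pred.astype(bool))
            if gt_comps:
                assert ltpr == pytest.approx(ref_ltpr)
            if pr_comps:
                assert lfpr == pytest.approx(ref_lfpr)

    def test_threshold_monotonicity(self, rng):
        """Raising the overlap threshold never raises LTPR nor lowers
        LFPR."""
        gt = (rng.random((16, 16, 16)) < 0.08).astype(np.uint8)
        pred = (rng.random((16, 16, 16)) < 0.08).astype(np.uint8)
        gm, pm = mask_of(gt), mask_of(pred)
        gl, pl = find_lesions(gm), find_lesions(pm)
        prev_ltpr, prev_lfpr = 1.1, -0.1
        for thr in (0.05, 0.1, 0.3, 0.6, 0.9):
            ltpr, _, lfpr = detection_metrics(gl, pl, gm, pm, threshold=thr)
            if not np.isnan(ltpr):
                assert ltpr <= prev_ltpr + 1e-12
                prev_ltpr = ltpr
            if not np.isnan(lfpr):
                assert lfpr >= prev_lfpr - 1e-12
                prev_lfpr = lfpr


class TestSizeStratified:
    def test_boundary_bin_assignment(self):
        gt = np.zeros((16, 16, 16), dtype=np.uint8)
        gt[1, 1, 1:11] = 1       # 10 voxels -> bin 3-10
        gt[5, 5:6, 1:12] = 1     # 11 voxels -> bin 11-50
        gm = mask_of(gt)
        out = size_stratified(find_lesions(gm), [], gm,
                              mask_of(np.zeros_like(gt)))
        assert out["3-10"]["n_gt"] == 1
        assert out["11-50"]["n_gt"] == 1
        assert out["51-inf"]["n_gt"] == 0
        assert np.isnan(out["51-inf"]["ltpr"])

    def test_all_small_detected(self):
        gt = np.zeros((16, 16, 16), dtype=np.uint8)
        gt[1, 1, 1:6] = 1
        gm = mask_of(gt)
        out = size_stratified(find_lesions(gm), find_lesions(gm), gm, gm)
        assert out["3-10"]["ltpr"] == 1.0
        assert np.isnan(out["11-50"]["ltpr"])

    def test_matches_brute_force_recount(self, rng):
        gt = (rng.random((16, 16, 16)) < 0.15).astype(np.uint8)
        pred = (rng.random((16, 16, 16)) < 0.15).astype(np.uint8)
        gm, pm = mask_of(gt), mask_of(pred)
        gl, pl = find_lesions(gm), find_lesions(pm)
        out = size_stratified(gl, pl, gm, pm)
        for (lo, hi), key in zip(DEFAULT_SIZE_BINS,
                                 ("3-10", "11-50", "51-inf")):
            sel = [c for c in gl if lo <= c.size_voxels
                   and (hi is None or c.size_voxels <= hi)]
            assert out[key]["n_gt"] == len(sel)
            if sel:
                det = sum(
                    1 for c in sel
                    if sum(pred[tuple(v)] for v in c.voxels)
                    / c.size_voxels >= 0.1)
                assert out[key]["ltpr"] == pytest.approx(det / len(sel))


class TestCohortCorrelations:
    def _reports(self, gt_vols, pred_vols):
        reps = []
        for g, p in zip(gt_vols, pred_vols):
            reps.append(type("R", (), {
                "gt_tlv_uL": g, "pred_tlv_uL": p,
                "gt_count": int(g // 10), "pred_count": int(p // 10)})())
        return reps

    def test_perfect_agreement(self):
        v = np.linspace(10, 100, 10)
        r_vol, r_count = cohort_correlations(self._reports(v, v))
        assert r_vol == pytest.approx(1.0)
        assert r_count == pytest.approx(1.0)

    def test_scale_invariance(self):
        v = np.linspace(10, 100, 10)
        r_vol, _ = cohort_correlations(self._reports(v, 2 * v))
        assert r_vol == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        a = rng.random(20) * 100
        b = rng.random(20) * 100
        r_vol, _ = cohort_correlations(self._reports(a, b))
        ref = (((a - a.mean()) * (b - b.mean())).sum()
               / np.sqrt(((a - a.mean())**2).sum()
                         * ((b - b.mean())**2).sum()))
        assert r_vol == pytest.approx(ref)

    def test_too_few_scans(self):
        with pytest.raises(ValueError):
            cohort_correlations(self._reports([1, 2], [1, 2]))


class TestEvaluateScan:
    def test_report_consistency(self, rng):
        gt = (rng.random((16, 16, 16)) < 0.1).astype(np.uint8)
        pred = (rng.random((16, 16, 16)) < 0.1).astype(np.uint8)
        rep = evaluate_scan(mask_of(gt), mask_of(pred))
        if not np.isnan(rep.lppv):
            assert rep.lppv == pytest.approx(1 - rep.lfpr)
        assert rep.gt_tlv_uL == pytest.approx(gt.sum() * 3.0)
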