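"""Voxel- and lesion-wise evaluation of binary segmentations.

Lesions are maximal 18-connected components (neighbours sharing a face or
an edge — at most two coordinate offsets nonzero — but not a corner) of at
least 3 voxels; smaller components are excluded from all lesion-wise
statistics, mirroring the common MS convention regardless of voxel size.

Detection uses a 10% mask-overlap rule: a ground-truth lesion is detected
iff at least 10% of its voxels are covered by the predicted foreground, and
a predicted lesion is a false positive iff less than 10% of its voxels
overlap the ground-truth foreground.  Overlap is computed against the
opposing *mask*, not against paired components, so one-to-many splits and
merges are handled gracefully.

Undefined rates (no GT lesions, no predicted lesions, empty prediction) are
returned as NaN and excluded from cohort means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LesionMask, assert_same_grid

__all__ = [
    "LesionComponent", "MetricReport", "structure_18", "find_lesions",
    "segmentation_metrics", "detection_metrics", "size_stratified",
    "cohort_correlations", "evaluate_scan", "DEFAULT_SIZE_BINS",
]

MIN_LESION_VOXELS = 3
DETECTION_OVERLAP = 0.1
DEFAULT_SIZE_BINS = ((3, 10), (11, 50), (51, None))


def structure_18() -> np.ndarray:
    """3x3x3 stencil of 18-connectivity: <= 2 nonzero coordinate offsets."""
    s = np.zeros((3, 3, 3), dtype=bool)
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if abs(dz) + abs(dy) + abs(dx) <= 2:
                    s[dz + 1, dy + 1, dx + 1] = True
    return s


@dataclass
class LesionComponent:
    """One connected lesion."""

    id: int
    voxels: np.ndarray            # (n, 3) int array of (z, y, x)
    size_voxels: int
    volume_uL: float

    @property
    def min_voxel(self) -> tuple[int, int, int]:
        return tuple(self.voxels[0])


def find_lesions(mask: LesionMask, min_size: int = MIN_LESION_VOXELS,
                 connectivity: int = 18) -> list[LesionComponent]:
    """Connected lesion components, size-filtered, deterministically ordered
    by lexicographically smallest member voxel."""
    if connectivity == 18:
        structure = structure_18()
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    else:
        raise ValueError(f"unsupported connectivity {connectivity}")
    labeled, n = ndimage.label(mask.labels, structure=structure)
    vox_vol = mask.grid.voxel_volume_uL
    comps = []
    for lbl in range(1, n + 1):
        coords = np.argwhere(labeled == lbl)
        if len(coords) < min_size:
            continue
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
        coords = coords[order]
        comps.append(LesionComponent(
            id=0, voxels=coords, size_voxels=len(coords),
            volume_uL=len(coords) * vox_vol))
    comps.sort(key=lambda c: c.min_voxel)
    for i, c in enumerate(comps):
        c.id = i
    return comps


def segmentation_metrics(gt: LesionMask, pred: LesionMask):
    """Voxel-level (DC, PPV, TPR).

    Both masks empty: all three are 1 by convention.  Empty prediction with
    nonempty GT: PPV is NaN (flagged, excluded from cohort means).
    """
    assert_same_grid([gt, pred])
    g = gt.labels.astype(bool)
    p = pred.labels.astype(bool)
    tp = int((g & p).sum())
    fp = int((~g & p).sum())
    fn = int((g & ~p).sum())
    if tp + fp + fn == 0:
        return 1.0, 1.0, 1.0
    dc = 2 * tp / (2 * tp + fp + fn)
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    tpr = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return dc, ppv, tpr


def _overlap_fraction(comp: LesionComponent, mask_bool: np.ndarray) -> float:
    z, y, x = comp.voxels.T
    return float(mask_bool[z, y, x].sum()) / comp.size_voxels


def detection_metrics(gt_lesions, pred_lesions, gt_mask: LesionMask,
                      pred_mask: LesionMask,
                      threshold: float = DETECTION_OVERLAP):
    """Lesion-wise (LTPR, LPPV, LFPR) under the 10% mask-overlap rule.

    Undefined rates (no GT lesions -> LTPR; no predicted lesions ->
    LPPV/LFPR) are NaN.
    """
    pred_bool = pred_mask.labels.astype(bool)
    gt_bool = gt_mask.labels.astype(bool)
    detected = [_overlap_fraction(c, pred_bool) >= threshold
                for c in gt_lesions]
    false_pos = [_overlap_fraction(c, gt_bool) < threshold
                 for c in pred_lesions]
    ltpr = (sum(detected) / len(gt_lesions)) if gt_lesions else float("nan")
    if pred_lesions:
        lfpr = sum(false_pos) / len(pred_lesions)
        lppv = 1.0 - lfpr
    else:
        lfpr = lppv = float("nan")
    return ltpr, lppv, lfpr


def _lesion_dice(comp: LesionComponent, gt_bool: np.ndarray,
                 pred_bool: np.ndarray, margin: int = 1) -> float:
    """Per-lesion dice on the union bounding region of the GT lesion and its
    overlapping prediction."""
    lo = comp.voxels.min(axis=0)
    hi = comp.voxels.max(axis=0) + 1
    # grow the box to include any predicted component touching the lesion
    lo = np.maximum(lo - margin, 0)
    hi = np.minimum(hi + margin, gt_bool.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    g = np.zeros_like(gt_bool[sl])
    zyx = comp.voxels - lo
    g[zyx[:, 0], zyx[:, 1], zyx[:, 2]] = True
    p = pred_bool[sl]
    denom = g.sum() + p.sum()
    return 2.0 * float((g & p).sum()) / denom if denom else 1.0


def size_stratified(gt_lesions, pred_lesions, gt_mask: LesionMask,
                    pred_mask: LesionMask, bins=DEFAULT_SIZE_BINS,
                    threshold: float = DETECTION_OVERLAP) -> dict:
    """Per-size-bin lesion DC, LTPR (by GT lesion size) and LFPR (by
    predicted lesion size).  Empty bins give NaN, not zero."""
    gt_bool = gt_mask.labels.astype(bool)
    pred_bool = pred_mask.labels.astype(bool)

    def in_bin(size, b):
        lo, hi = b
        return size >= lo and (hi is None or size <= hi)

    out = {}
    for b in bins:
        gts = [c for c in gt_lesions if in_bin(c.size_voxels, b)]
        preds = [c for c in pred_lesions if in_bin(c.size_voxels, b)]
        if gts:
            det = [_overlap_fraction(c, pred_bool) >= threshold for c in gts]
            ltpr = sum(det) / len(gts)
            ldc = float(np.mean([_lesion_dice(c, gt_bool, pred_bool)
                                 for c in gts]))
        else:
            ltpr = ldc = float("nan")
        if preds:
            fp = [_overlap_fraction(c, gt_bool) < threshold for c in preds]
            lfpr = sum(fp) / len(preds)
        else:
            lfpr = float("nan")
        key = f"{b[0]}-{b[1] if b[1] is not None else 'inf'}"
        out[key] = {"lesion_dc": ldc, "ltpr": ltpr, "lfpr": lfpr,
                    "n_gt": len(gts), "n_pred": len(preds)}
    return out


@dataclass
class MetricReport:
    """Per-scan segmentation + detection summary (Table-2-style columns)."""

    dc: float
    ppv: float
    tpr: float
    ltpr: float
    lppv: float
    lfpr: float
    gt_count: int
    pred_count: int
    gt_tlv_uL: float
    pred_tlv_uL: float


def evaluate_scan(gt: LesionMask, pred: LesionMask,
                  min_size: int = MIN_LESION_VOXELS,
                  threshold: float = DETECTION_OVERLAP) -> MetricReport:
    dc, ppv, tpr = segmentation_metrics(gt, pred)
    gt_les = find_lesions(gt, min_size=min_size)
    pred_les = find_lesions(pred, min_size=min_size)
    ltpr, lppv, lfpr = detection_metrics(gt_les, pred_les, gt, pred,
                                         threshold=threshold)
    return MetricReport(
        dc=dc, ppv=ppv, tpr=tpr, ltpr=ltpr, lppv=lppv, lfpr=lfpr,
        gt_count=len(gt_les), pred_count=len(pred_les),
        gt_tlv_uL=gt.tlv_uL, pred_tlv_uL=pred.tlv_uL)


def cohort_correlations(reports: list[MetricReport]):
    """Pearson r of predicted-vs-GT total lesion volumes and counts.

    Requires >= 3 scans; zero variance in either vector gives NaN.
    """
    if len(reports) < 3:
        raise ValueError("need at least 3 scans for cohort correlations")

    def pearson(a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    r_vol = pearson([r.gt_tlv_uL for r in reports],
                    [r.pred_tlv_uL for r in reports])
    r_count = pearson([r.gt_count for r in reports],
                      [r.pred_count for r in reports])
    return r_vol, r_count
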