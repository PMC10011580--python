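"""Full-volume prediction: sliding-window stitching, MC dropout, ensembling.

A volume is covered by 20%-overlap patches; each patch is predicted by the
finest network head and overlapping voxels are averaged (count-normalised
accumulation).  Monte-Carlo dropout repeats the stitched prediction with
dropout kept active (n = 10 by default); the cross-validated fold models
contribute 10 samples each, and the fold x repeat stack is summarised by a
voxelwise mean probability and standard deviation.  The mean map is
binarised at 0.5 with the tie (exactly 0.5) counted as foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PatchPlan, plan_patches
from .volume_io import LesionMask, MultimodalVolume, ProbabilityMap, VolumeGrid

__all__ = ["EnsemblePrediction", "stitch", "predict_volume", "mc_predict",
           "ensemble", "N_MC_DEFAULT"]

N_MC_DEFAULT = 10


@dataclass
class EnsemblePrediction:
    mean_prob: ProbabilityMap
    uncertainty: np.ndarray       # per-voxel SD over samples
    n_samples: int
    mask: LesionMask


def stitch(patch_probs, grid: VolumeGrid,
           padding=((0, 0), (0, 0), (0, 0))) -> ProbabilityMap:
    """Average overlapping patch probabilities onto the full grid.

    ``patch_probs`` is a list of ``(origin, prob_patch)`` in padded-grid
    coordinates.  Every voxel of the (padded) grid must be covered.
    """
    padded_shape = tuple(s + p0 + p1
                         for s, (p0, p1) in zip(grid.shape, padding))
    acc = np.zeros(padded_shape, dtype=np.float64)
    cnt = np.zeros(padded_shape, dtype=np.int32)
    for origin, patch in patch_probs:
        z, y, x = origin
        pz, py, px = patch.shape
        acc[z:z + pz, y:y + py, x:x + px] += patch
        cnt[z:z + pz, y:y + py, x:x + px] += 1
    if (cnt == 0).any():
        raise ValueError("stitching plan leaves uncovered voxels")
    probs = acc / cnt
    sl = tuple(slice(p0, p0 + s) for s, (p0, _p1) in zip(grid.shape, padding))
    return ProbabilityMap(grid, np.clip(probs[sl], 0.0, 1.0))


def predict_volume(model, volume: MultimodalVolume,
                   plan: PatchPlan | None = None,
                   batch_size: int = 4) -> ProbabilityMap:
    """Single deterministic stitched forward pass (finest head only)."""
    if plan is None:
        plan = plan_patches(volume.grid)
    stack = volume.stack()
    if any(p != (0, 0) for p in plan.padding):
        stack = np.pad(stack, ((0, 0),) + tuple(plan.padding))
    pz, py, px = plan.patch_shape
    outputs = []
    origins = plan.origins
    for i in range(0, len(origins), batch_size):
        chunk = origins[i:i + batch_size]
        batch = np.stack([stack[:, z:z + pz, y:y + py, x:x + px]
                          for (z, y, x) in chunk])
        preds = model(batch)[0].data[:, 0]  # finest head, squeeze channel
        outputs.extend(zip(chunk, preds))
    return stitch(outputs, volume.grid, plan.padding)


def mc_predict(model, volume: MultimodalVolume, n: int = N_MC_DEFAULT,
               seed: int = 0, plan: PatchPlan | None = None) -> list[ProbabilityMap]:
    """n stitched predictions with dropout active (deterministic per seed).

    With ``dropout_rate == 0`` all n maps are identical.
    """
    model.eval()
    model.set_mc_dropout(True, seed=seed)
    try:
        maps = [predict_volume(model, volume, plan=plan) for _ in range(n)]
    finally:
        model.set_mc_dropout(False)
    return maps


def ensemble(fold_models, volume: MultimodalVolume,
             n_mc: int = N_MC_DEFAULT, seed: int = 0,
             threshold: float = 0.5,
             plan: PatchPlan | None = None) -> EnsemblePrediction:
    """Cross-fold MC-dropout ensemble: folds x n_mc stitched samples.

    Mean and per-voxel SD over all samples; mask = (mean >= threshold).
    """
    if not fold_models:
        raise ValueError("need at least one fold model")
    samples = []
    for k, model in enumerate(fold_models):
        model_obj = getattr(model, "model", model)  # accept ModelHandle
        for pm in mc_predict(model_obj, volume, n=n_mc,
                             seed=seed + 1000 * k, plan=plan):
            samples.append(pm.probs)
    arr = np.stack(samples).astype(np.float64)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)
    mean_map = ProbabilityMap(volume.grid, mean)
    return EnsemblePrediction(
        mean_prob=mean_map, uncertainty=sd, n_samples=len(samples),
        mask=mean_map.binarize(threshold))
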