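"""Intensity normalisation, lesion-aware patch extraction, augmentation.

Normalisation pipeline per channel, computed over nonzero (brain) voxels of
the skull-stripped volume: min-max rescale to [0, 1], clip to the 1st-99th
percentile band, then z-score with the mean/SD of the in-band voxels.
Percentiles are computed per volume (configurable via ``per_channel_stats``
callers if a dataset-level policy is wanted).

Patch extraction slides a 32x96x96 window with 20% overlap; training and
validation keep only patches containing at least one lesion voxel (negative
patches are excluded).  Augmentation applies, with probability 0.5, a random
in-plane affine followed by an elastic deformation, identically to image and
label (linear vs nearest-neighbour interpolation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import (CHANNEL_ORDER, LesionMask, MultimodalVolume,
                        VolumeGrid, assert_same_grid)

__all__ = [
    "Patch", "PatchPlan", "AugmentParams", "NormalizationError", "normalize",
    "plan_patches", "extract_training_patches", "augment",
]

DEFAULT_PATCH_SHAPE = (32, 96, 96)
DEFAULT_OVERLAP = 0.2


class NormalizationError(ValueError):
    """Raised for degenerate (constant) channels."""


@dataclass
class Patch:
    """One network input patch: (C, z, y, x) data plus optional label."""

    data: np.ndarray
    origin: tuple[int, int, int]
    label: np.ndarray | None = None

    def __post_init__(self):
        self.origin = tuple(int(o) for o in self.origin)
        if any(o < 0 for o in self.origin):
            raise ValueError("patch origin must be non-negative")
        if self.label is not None and self.label.shape != self.data.shape[1:]:
            raise ValueError("label shape must match patch spatial shape")

    @property
    def n_foreground(self) -> int:
        return 0 if self.label is None else int(self.label.sum())


@dataclass
class PatchPlan:
    patch_shape: tuple[int, int, int]
    overlap_fraction: float
    origins: list[tuple[int, int, int]]
    padding: tuple[tuple[int, int], ...] = field(
        default_factory=lambda: ((0, 0), (0, 0), (0, 0)))


def _axis_origins(length: int, patch: int, overlap: float) -> list[int]:
    """1D sliding origins: stride ceil(patch*(1-overlap)), last clamped."""
    stride = max(1, math.ceil(patch * (1.0 - overlap)))
    origins = list(range(0, max(length - patch, 0) + 1, stride))
    last = length - patch
    if origins[-1] != last:
        origins.append(last)
    return origins


def plan_patches(grid: VolumeGrid | tuple, patch_shape=DEFAULT_PATCH_SHAPE,
                 overlap_fraction: float = DEFAULT_OVERLAP) -> PatchPlan:
    """Covering sliding-window plan (z-major sorted origins).

    Volumes smaller than the patch along an axis are zero-padded
    symmetrically; the returned plan records the per-axis padding.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    shape = grid.shape if isinstance(grid, VolumeGrid) else tuple(grid)
    patch_shape = tuple(int(p) for p in patch_shape)
    padding = []
    padded = []
    for s, p in zip(shape, patch_shape):
        if s >= p:
            padding.append((0, 0))
            padded.append(s)
        else:
            lo = (p - s) // 2
            hi = p - s - lo
            padding.append((lo, hi))
            padded.append(p)
    axes = [_axis_origins(s, p, overlap_fraction)
            for s, p in zip(padded, patch_shape)]
    origins = [(z, y, x) for z in axes[0] for y in axes[1] for x in axes[2]]
    return PatchPlan(patch_shape, overlap_fraction, origins, tuple(padding))


def normalize(volume: MultimodalVolume, p_lo: float = 1.0, p_hi: float = 99.0,
              sigma_guard: float = 1e-8) -> MultimodalVolume:
    """Per-channel min-max rescale, percentile clip and z-score.

    Statistics are taken over nonzero voxels only (background of
    skull-stripped volumes is zero and would otherwise dominate).
    """
    out = {}
    for name in CHANNEL_ORDER:
        x = volume.channels[name].astype(np.float64)
        brain = x != 0
        if not brain.any():
            raise NormalizationError(f"channel {name}: no nonzero voxels")
        vals = x[brain]
        vmin, vmax = vals.min(), vals.max()
        if vmax - vmin <= sigma_guard:
            raise NormalizationError(f"channel {name}: constant intensities")
        x = np.where(brain, (x - vmin) / (vmax - vmin), 0.0)
        vals = x[brain]
        lo, hi = np.percentile(vals, [p_lo, p_hi])
        x = np.where(brain, np.clip(x, lo, hi), 0.0)
        in_band = vals[(vals >= lo) & (vals <= hi)]
        mu = in_band.mean()
        sd = in_band.std()
        if sd <= sigma_guard:
            raise NormalizationError(
                f"channel {name}: zero variance within percentile band")
        out[name] = np.where(brain, (x - mu) / sd, 0.0).astype(np.float32)
    return MultimodalVolume(volume.grid, out)


def extract_training_patches(volume: MultimodalVolume, mask: LesionMask,
                             plan: PatchPlan | None = None) -> list[Patch]:
    """Extract patches that contain at least one lesion voxel.

    Returns an empty list for lesion-free volumes (the caller decides how to
    handle subjects without lesions).
    """
    assert_same_grid([volume, mask])
    if plan is None:
        plan = plan_patches(volume.grid)
    stack = volume.stack()
    labels = mask.labels
    if any(p != (0, 0) for p in plan.padding):
        pad = ((0, 0),) + plan.padding
        stack = np.pad(stack, pad)
        labels = np.pad(labels, plan.padding)
    pz, py, px = plan.patch_shape
    patches = []
    for (z, y, x) in plan.origins:
        lab = labels[z:z + pz, y:y + py, x:x + px]
        if lab.any():
            patches.append(Patch(
                data=stack[:, z:z + pz, y:y + py, x:x + px].copy(),
                origin=(z, y, x), label=lab.copy()))
    return patches


@dataclass
class AugmentParams:
    """Magnitudes for on-the-fly augmentation (conservative defaults)."""

    probability: float = 0.5
    max_rotation_deg: float = 10.0   # in-plane
    scale_range: tuple[float, float] = (0.9, 1.1)
    max_translation_vox: float = 5.0  # in-plane
    elastic_sigma_vox: float = 4.0
    elastic_max_inplane_vox: float = 3.0
    elastic_max_throughplane_vox: float = 1.0


def _affine_matrix(rng: np.random.Generator, params: AugmentParams):
    """In-plane (y,x) rotation+scale+translation; z untouched."""
    theta = np.deg2rad(rng.uniform(-params.max_rotation_deg,
                                   params.max_rotation_deg))
    s = rng.uniform(*params.scale_range)
    c, sn = np.cos(theta), np.sin(theta)
    rot = np.array([[1, 0, 0],
                    [0, c / s, -sn / s],
                    [0, sn / s, c / s]])
    t = np.array([0.0,
                  rng.uniform(-params.max_translation_vox,
                              params.max_translation_vox),
                  rng.uniform(-params.max_translation_vox,
                              params.max_translation_vox)])
    return rot, t


def _elastic_field(shape, rng: np.random.Generator, params: AugmentParams):
    disp = []
    caps = (params.elastic_max_throughplane_vox,
            params.elastic_max_inplane_vox, params.elastic_max_inplane_vox)
    for cap in caps:
        f = rng.standard_normal(shape)
        f = ndimage.gaussian_filter(f, params.elastic_sigma_vox)
        peak = np.abs(f).max()
        if peak > 0:
            f = f / peak * cap
        disp.append(f)
    return disp


def augment(patch: Patch, rng_seed: int | np.random.Generator,
            params: AugmentParams | None = None) -> Patch:
    """Randomly augment a training patch (identical warp on image & label).

    With probability ``params.probability`` applies a random in-plane affine
    (rotation, scale, translation) followed by an elastic deformation built
    from a Gaussian-smoothed displacement field.  Image channels use linear
    interpolation; the label uses nearest neighbour and stays binary.
    """
    if patch.label is None:
        raise ValueError("augment requires a training patch with a label")
    params = params or AugmentParams()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if rng.random() >= params.probability:
        return patch
    shape = patch.label.shape
    rot, t = _affine_matrix(rng, params)
    disp = _elastic_field(shape, rng, params)
    center = (np.array(shape) - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                             indexing="ij")
    coords = np.stack([zz, yy, xx])          # output voxel coordinates
    rel = coords - center[:, None, None, None]
    src = np.tensordot(rot, rel, axes=1) + center[:, None, None, None] \
        + np.asarray(t)[:, None, None, None]
    src = src + np.stack(disp)
    data = np.stack([
        ndimage.map_coordinates(ch, src, order=1, mode="constant")
        for ch in patch.data]).astype(np.float32)
    label = ndimage.map_coordinates(patch.label, src, order=0,
                                    mode="constant").astype(np.uint8)
    return Patch(data=data, origin=patch.origin, label=label)
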