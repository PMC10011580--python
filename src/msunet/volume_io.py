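"""Volume containers and NIfTI I/O.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)`` — slices, rows, columns — 0-based;
* voxel spacing is quoted ``(z, y, x)`` in mm, so the clinical-trial
  resolution of ~1 x 1 x 3 mm³ axial acquisitions is ``spacing_mm=(3, 1, 1)``;
* 1 mm³ = 1 μL, hence the voxel volume at that resolution is 3 μL and a
  10-voxel lesion is exactly 30 μL;
* the NIfTI affine is carried through reads/writes but never used for
  resampling — inputs are assumed co-registered and skull-stripped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

CHANNEL_ORDER = ("T1p", "T2w", "FLAIR")

__all__ = [
    "CHANNEL_ORDER", "VolumeGrid", "MultimodalVolume", "LesionMask",
    "ProbabilityMap", "GridMismatchError", "read_volume", "write_volume",
    "assert_same_grid",
]


class GridMismatchError(ValueError):
    """Raised when grid-bearing objects disagree on shape or spacing."""


@dataclass(frozen=True)
class VolumeGrid:
    """Discrete 3D sampling grid: shape (z,y,x), spacing in mm, affine."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (3.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        if self.affine is None:
            object.__setattr__(self, "affine", np.eye(4))

    @property
    def voxel_volume_uL(self) -> float:
        """Volume of one voxel in microlitres (1 mm³ = 1 μL)."""
        return float(np.prod(self.spacing_mm))

    def compatible(self, other: "VolumeGrid", tol_mm: float = 1e-4) -> bool:
        return (self.shape == other.shape
                and all(abs(a - b) <= tol_mm
                        for a, b in zip(self.spacing_mm, other.spacing_mm)))


@dataclass
class LesionMask:
    """Binary lesion labels on a grid."""

    grid: VolumeGrid
    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise GridMismatchError(
                f"labels shape {labels.shape} != grid shape {self.grid.shape}")
        uniq = np.unique(labels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be binary, found {uniq[:5]}")
        self.labels = labels.astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.labels.sum())

    @property
    def tlv_uL(self) -> float:
        """Total lesion volume in μL."""
        return self.n_foreground * self.grid.voxel_volume_uL


@dataclass
class ProbabilityMap:
    """Voxelwise foreground probabilities in [0, 1] on a grid."""

    grid: VolumeGrid
    probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=np.float32)
        if probs.shape != self.grid.shape:
            raise GridMismatchError(
                f"probs shape {probs.shape} != grid shape {self.grid.shape}")
        if probs.min() < 0 or probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.probs = probs

    def binarize(self, threshold: float = 0.5) -> LesionMask:
        """Threshold with prob >= threshold counted as foreground."""
        return LesionMask(self.grid, (self.probs >= threshold).astype(np.uint8))


@dataclass
class MultimodalVolume:
    """Ordered (T1p, T2w, FLAIR) intensity channels sharing one grid."""

    grid: VolumeGrid
    channels: dict[str, np.ndarray]

    def __post_init__(self):
        if tuple(self.channels) != CHANNEL_ORDER:
            # accept any insertion order but store canonically
            missing = set(CHANNEL_ORDER) - set(self.channels)
            if missing:
                raise ValueError(f"missing channels: {sorted(missing)}")
            self.channels = {k: self.channels[k] for k in CHANNEL_ORDER}
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=np.float32)
            if arr.shape != self.grid.shape:
                raise GridMismatchError(
                    f"channel {name} shape {arr.shape} != grid {self.grid.shape}")
            self.channels[name] = arr

    def stack(self) -> np.ndarray:
        """(3, z, y, x) array in canonical channel order."""
        return np.stack([self.channels[k] for k in CHANNEL_ORDER])


def _grid_from_img(img) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    # nibabel axes are (x, y, z); our convention is (z, y, x)
    return VolumeGrid(shape=img.shape[::-1], spacing_mm=tuple(zooms[::-1]),
                      affine=np.asarray(img.affine))


def read_volume(path, expected_kind: str = "intensity",
                binary_tol: float = 1e-6):
    """Read a 3D NIfTI file as an intensity array or a lesion mask.

    Returns ``(grid, array)`` for ``expected_kind="intensity"`` or a
    :class:`LesionMask` for ``expected_kind="mask"``.  Mask files are checked
    to be binary after rounding within ``binary_tol``.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {img.shape}")
    data = np.asanyarray(img.dataobj).T  # (x,y,z) -> (z,y,x)
    grid = _grid_from_img(img)
    if expected_kind == "mask":
        rounded = np.rint(data)
        if np.max(np.abs(data - rounded)) > binary_tol or \
                not np.all(np.isin(np.unique(rounded), (0, 1))):
            raise ValueError(f"{path}: mask content is not binary")
        return LesionMask(grid, rounded.astype(np.uint8))
    if expected_kind != "intensity":
        raise ValueError(f"unknown expected_kind {expected_kind!r}")
    return grid, data.astype(np.float32)


def write_volume(path, grid: VolumeGrid, array: np.ndarray) -> None:
    """Write a (z,y,x) array to NIfTI using the grid's spacing and affine."""
    path = Path(path)
    arr = np.asarray(array)
    if arr.shape != grid.shape:
        raise GridMismatchError(f"array shape {arr.shape} != grid {grid.shape}")
    img = nib.Nifti1Image(np.ascontiguousarray(arr.T), grid.affine)
    img.header.set_zooms(tuple(grid.spacing_mm[::-1]))
    nib.save(img, str(path))


def assert_same_grid(items, tol_mm: float = 1e-4) -> None:
    """Check that all grid-bearing objects share shape and spacing.

    Raises :class:`GridMismatchError` naming the first offending item.
    """
    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least two items to compare")
    grids = [it if isinstance(it, VolumeGrid) else it.grid for it in items]
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if not ref.compatible(g, tol_mm=tol_mm):
            raise GridMismatchError(
                f"item {i} grid (shape={g.shape}, spacing={g.spacing_mm}) "
                f"does not match item 0 (shape={ref.shape}, "
                f"spacing={ref.spacing_mm})")
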