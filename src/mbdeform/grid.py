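"""Image grids, masks and displacement fields.

All spatial operations in the package share one convention: a 3-D scalar
array indexed (x, y, z), a positive voxel spacing in mm, and a world origin
in mm, so that voxel (i, j, k) sits at ``origin + (i, j, k) * spacing``.
Direction cosines are assumed axis-aligned (identity); inputs with oblique
affines must be resampled upstream.

Displacement fields carry one 3-vector (mm, x/y/z order) per voxel of the
grid they are defined on and are serialized as 4-D NIfTI with the last axis
holding the vector component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "DisplacementField", "load_volume", "load_mask", "load_field"]


@dataclass
class ImageVolume:
    """A 3-D scalar volume on a regular axis-aligned grid (mm units)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def axis_coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (1-D arrays), suitable for broadcasting."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a], dtype=float)
            for a in range(3)
        )

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert (..., 3) world coordinates to fractional voxel indices."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine()), str(path))


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors in mm, on the grid it maps *from*.

    ``vectors`` has shape (nx, ny, nz, 3); a zero field maps every point to
    itself. ``warp_point(x) = x + u(x)``.
    """

    vectors: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(f"expected (nx, ny, nz, 3), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean norm in mm."""
        return np.sqrt(np.sum(self.vectors**2, axis=-1))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def save(self, path: str | Path) -> None:
        nib.save(
            nib.Nifti1Image(np.asarray(self.vectors, dtype=np.float32), self.affine()), str(path)
        )


def _check_axis_aligned(affine: np.ndarray, path: str | Path) -> None:
    rot = affine[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off) > 1e-6 * max(1.0, np.abs(rot).max())):
        raise ValueError(f"{path}: oblique affine not supported; resample to axis-aligned first")
    if np.any(np.diag(rot) <= 0):
        raise ValueError(f"{path}: negative/zero affine diagonal; reorient to +x/+y/+z first")


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    _check_axis_aligned(aff, path)
    data = np.asarray(img.get_fdata(), dtype=float)
    return ImageVolume(data, tuple(np.diag(aff)[:3]), tuple(aff[:3, 3]))


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask; any voxel > 0.5 counts as foreground."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5


def load_field(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    aff = img.affine
    _check_axis_aligned(aff, path)
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 5:  # NIfTI "vector" intent stores (x,y,z,1,3)
        data = data[:, :, :, 0, :]
    return DisplacementField(data, tuple(np.diag(aff)[:3]), tuple(aff[:3, 3]))
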