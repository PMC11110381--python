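"""Core in-memory containers: 3-D image volumes and dense displacement fields.

Conventions used across the package:

* voxel grids are indexed ``(x, y, z)``, 0-based;
* displacements are stored in voxel units, component order ``(dx, dy, dz)``;
* the full spatial mapping is ``phi(x) = x + s(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "DeformationField"]


@dataclass
class ImageVolume:
    """A 3-D scalar voxel grid with physical metadata.

    Parameters
    ----------
    voxels
        3-D array of intensities, indexed ``(x, y, z)``. Must be finite.
    spacing
        Millimetres per voxel along each axis; strictly positive.
    origin
        Physical position of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"ImageVolume requires a 3-D grid, got shape {self.voxels.shape}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("ImageVolume intensities must all be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.voxels.copy(), self.spacing, self.origin)


@dataclass
class DeformationField:
    """A dense voxel-displacement field ``s`` of shape ``(X, Y, Z, 3)``.

    Component order is ``(dx, dy, dz)`` and units are voxels, so the mapping
    applied by the warping layer is ``phi(x) = x + s(x)``.
    """

    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ValueError(
                "DeformationField requires shape (X, Y, Z, 3), got "
                f"{self.displacements.shape}"
            )
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacements must all be finite")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean displacement magnitude, in voxels."""
        return np.sqrt((self.displacements.astype(np.float64) ** 2).sum(axis=-1))

    def copy(self) -> "DeformationField":
        return DeformationField(self.displacements.copy())
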