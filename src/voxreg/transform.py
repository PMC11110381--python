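"""Spatial transformation: identity grid and warping by a displacement field.

``warp_volume`` evaluates the moving image at ``phi(x) = x + s(x)`` with
trilinear interpolation (nearest-neighbour for masks); sampling locations
outside the grid are clamped to the border (edge replication), which avoids
injecting artificial zeros into similarity windows near the boundary.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import DeformationField, ImageVolume

__all__ = ["identity_grid", "warp_volume", "warp_mask", "zero_field", "invert_field"]


def identity_grid(shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel-coordinate grid ``g`` with ``g[i, j, k] = (i, j, k)``.

    Returns an array of shape ``(X, Y, Z, 3)`` in voxel units.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"shape must be 3 positive integers, got {shape}")
    axes = [np.arange(s, dtype=np.float64) for s in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def zero_field(shape: tuple[int, int, int]) -> DeformationField:
    """The identity transform: a field of all-zero displacements."""
    return DeformationField(np.zeros(tuple(shape) + (3,)))


def _as_voxels(vol) -> np.ndarray:
    return vol.voxels if isinstance(vol, ImageVolume) else np.asarray(vol)


def warp_volume(vol, field: DeformationField, mode: str = "trilinear"):
    """Resample ``vol`` at ``x + s(x)``: computes the warped image I_m o phi.

    Parameters
    ----------
    vol
        :class:`ImageVolume` or bare 3-D array (the moving image).
    field
        Displacement field matching the volume's spatial shape, voxel units.
    mode
        ``"trilinear"`` for intensities, ``"nearest"`` for label/mask volumes.

    Out-of-grid sample positions are clamped to the border.  Returns the same
    container type as the input.
    """
    vox = _as_voxels(vol)
    if vox.shape != field.spatial_shape:
        raise ValueError(
            f"field spatial shape {field.spatial_shape} does not match volume {vox.shape}"
        )
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    coords = identity_grid(vox.shape) + field.displacements
    out = ndimage.map_coordinates(
        vox,
        [coords[..., 0], coords[..., 1], coords[..., 2]],
        order=1 if mode == "trilinear" else 0,
        mode="nearest",
    )
    if isinstance(vol, ImageVolume):
        return ImageVolume(out, vol.spacing, vol.origin)
    return out


def invert_field(field: DeformationField, n_iter: int = 20, damping: float = 0.5) -> DeformationField:
    """Fixed-point approximation of the inverse displacement field.

    Solves ``inv(x + s(x)) = -s(x)`` by damped iteration
    ``inv <- (1 - alpha) * inv - alpha * s(y + inv(y))`` with trilinear
    sampling, starting from ``inv_0 = -s``.  The damping keeps the iteration
    stable where the local deformation gradient approaches 1; used by the
    phantom generator to build a moving image whose warp by ``s`` reproduces
    the fixed image up to interpolation error.
    """
    disp = field.displacements
    inv = -disp
    for _ in range(n_iter):
        sampled = np.stack(
            [warp_volume(disp[..., c], DeformationField(inv)) for c in range(3)],
            axis=-1,
        )
        inv = (1.0 - damping) * inv - damping * sampled
    return DeformationField(inv)


def warp_mask(mask, field: DeformationField, method: str = "nearest"):
    """Warp a 0/1 mask, preserving binarity.

    ``method="nearest"`` uses nearest-neighbour sampling; ``method="threshold"``
    warps trilinearly and re-binarises at 0.5.
    """
    vox = _as_voxels(mask)
    uniq = np.unique(vox)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask must contain only 0/1 values")
    if method == "nearest":
        out = warp_volume(vox.astype(np.float64), field, mode="nearest")
    elif method == "threshold":
        out = (warp_volume(vox.astype(np.float64), field, mode="trilinear") >= 0.5)
    else:
        raise ValueError(f"unknown mask warp method {method!r}")
    out = out.astype(np.uint8)
    if isinstance(mask, ImageVolume):
        return ImageVolume(out, mask.spacing, mask.origin)
    return out
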