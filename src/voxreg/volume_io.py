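"""NIfTI input/output, the preprocessing chain, and dataset splitting.

Volumes are exchanged as NIfTI-1 (``.nii``/``.nii.gz``); displacement fields as
4-D NIfTI with the last axis holding the ``(dx, dy, dz)`` components in voxel
units.  Preprocessing follows the standard chain for skull-stripped brain MR:
centred crop on the non-zero bounding box, trilinear resize, per-volume z-score
normalisation, then min-max rescale to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .volume import DeformationField, ImageVolume

__all__ = [
    "DatasetSplit",
    "load_volume",
    "save_volume",
    "load_field",
    "save_field",
    "preprocess_volume",
    "split_dataset",
    "write_split_manifest",
    "read_split_manifest",
]


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partition of subject identifiers."""

    train_ids: list
    val_ids: list
    test_ids: list
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split lists must be pairwise disjoint")


def _affine(vol: ImageVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vol.spacing
    aff[:3, 3] = vol.origin
    return aff


def load_volume(path: str | Path) -> ImageVolume:
    """Read a 3-D NIfTI file into an :class:`ImageVolume`.

    Spacing and origin are taken from the header; intensities are unmodified.
    A non-3-D image (or a trailing singleton 4th axis that is not 1) raises
    ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3-D image (shape {data.shape})")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(np.asarray(img.affine[:3, 3], dtype=float))
    return ImageVolume(np.asarray(data, dtype=np.float64), tuple(zooms), origin)


def save_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` to NIfTI; header spacing = ``vol.spacing``."""
    if not np.all(np.isfinite(vol.voxels)):
        raise ValueError("refusing to write non-finite intensities")
    img = nib.Nifti1Image(np.asarray(vol.voxels), _affine(vol))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(Path(path)))


def save_field(field: DeformationField, path: str | Path) -> None:
    """Write a displacement field as 4-D NIfTI (last axis = dx,dy,dz, voxels)."""
    img = nib.Nifti1Image(np.asarray(field.displacements, dtype=np.float32), np.eye(4))
    img.header["descrip"] = b"displacement field, voxel units, (dx,dy,dz) last axis"
    nib.save(img, str(Path(path)))


def load_field(path: str | Path) -> DeformationField:
    img = nib.load(str(Path(path)))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path} is not a 3-component 4-D field (shape {data.shape})")
    return DeformationField(data)


def _centered_crop(vox: np.ndarray, crop_dims: tuple[int, int, int]) -> np.ndarray:
    """Crop centred on the non-zero bounding box, clipped inside the grid.

    Falls back to the geometric centre when the volume is all-zero or the box
    exceeds the crop window along an axis.
    """
    nz = np.nonzero(vox)
    starts = []
    for ax, dim in enumerate(crop_dims):
        size = vox.shape[ax]
        if nz[0].size == 0:
            center = size / 2.0
        else:
            lo, hi = nz[ax].min(), nz[ax].max()
            center = (lo + hi + 1) / 2.0 if (hi - lo + 1) <= dim else size / 2.0
        start = int(round(center - dim / 2.0))
        starts.append(min(max(start, 0), size - dim))
    sl = tuple(slice(s, s + d) for s, d in zip(starts, crop_dims))
    return vox[sl]


def _resize(vox: np.ndarray, out_dims: tuple[int, int, int], order: int = 1) -> np.ndarray:
    """Align-corners resize by map_coordinates (order=1 trilinear, 0 nearest)."""
    if tuple(vox.shape) == tuple(out_dims):
        return vox.copy()
    axes = [
        np.linspace(0.0, s - 1.0, d) if d > 1 else np.array([(s - 1) / 2.0])
        for s, d in zip(vox.shape, out_dims)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(vox, coords, order=order, mode="nearest")


def preprocess_volume(
    vol: ImageVolume,
    crop_dims: tuple[int, int, int] = (224, 224, 155),
    out_dims: tuple[int, int, int] = (128, 128, 128),
) -> ImageVolume:
    """Crop -> resize -> z-score -> min-max rescale to [0, 1].

    The crop window is centred on the non-zero bounding box (peripheral voxels
    of a skull-stripped scan carry no information).  Normalisation statistics
    are per volume.  A constant input maps to all zeros.
    """
    crop_dims = tuple(int(c) for c in crop_dims)
    out_dims = tuple(int(o) for o in out_dims)
    if any(c > s for c, s in zip(crop_dims, vol.shape)):
        raise ValueError(f"crop_dims {crop_dims} exceed input dims {vol.shape}")
    if any(c <= 0 for c in crop_dims) or any(o <= 0 for o in out_dims):
        raise ValueError("crop_dims and out_dims must be positive")

    vox = _centered_crop(np.asarray(vol.voxels, dtype=np.float64), crop_dims)
    vox = _resize(vox, out_dims, order=1)

    # peak-to-peak guard: resampling a constant volume leaves ~1e-16 jitter
    # that z-scoring would blow up into noise
    ptp = vox.max() - vox.min()
    if ptp <= 1e-9 * max(1.0, float(np.abs(vox).max())):
        out = np.zeros(out_dims)
    else:
        sd = vox.std()
        vox = (vox - vox.mean()) / sd
        lo, hi = vox.min(), vox.max()
        out = (vox - lo) / (hi - lo)
    new_spacing = tuple(
        sp * (c / float(o)) for sp, c, o in zip(vol.spacing, crop_dims, out_dims)
    )
    return ImageVolume(out, new_spacing, vol.origin)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(ids: list, fractions: tuple[float, float, float], seed: int) -> DatasetSplit:
    """Random train/val/test split with round-half-up sizes, remainder to train.

    160 ids at fractions (0.64, 0.16, 0.20) give sizes (102, 26, 32).
    Deterministic given ``seed``.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be 3 nonnegative reals")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    n = len(ids)
    n_val = _round_half_up(fractions[1] * n)
    n_test = _round_half_up(fractions[2] * n)
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("rounded val+test sizes exceed the number of ids")

    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in perm]
    return DatasetSplit(
        train_ids=shuffled[:n_train],
        val_ids=shuffled[n_train : n_train + n_val],
        test_ids=shuffled[n_train + n_val :],
        seed=seed,
    )


def write_split_manifest(split: DatasetSplit, path: str | Path) -> None:
    """Plain-text manifest: one row per subject, columns ``id`` and ``split``."""
    lines = ["id\tsplit"]
    for name, id_list in (
        ("train", split.train_ids),
        ("val", split.val_ids),
        ("test", split.test_ids),
    ):
        lines += [f"{i}\t{name}" for i in id_list]
    Path(path).write_text("\n".join(lines) + "\n")


def read_split_manifest(path: str | Path, seed: int = 0) -> DatasetSplit:
    groups: dict[str, list] = {"train": [], "val": [], "test": []}
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        sid, name = line.rsplit("\t", 1)
        groups[name].append(sid)
    return DatasetSplit(groups["train"], groups["val"], groups["test"], seed=seed)
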