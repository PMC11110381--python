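"""Synthetic skull-stripped brain phantoms with known ground-truth deformation.

The generator emulates the gross appearance of a skull-stripped glioma MR
volume: an exactly-zero background, a smooth ellipsoidal "brain" whose
intensities lie in [0.2, 1], a handful of internal ellipsoidal tissue
structures of distinct intensity, one low-intensity spherical lesion, and
optional Gaussian noise inside the brain mask.  Registration pairs are
related by a known smooth displacement field, which makes endpoint error a
computable metric -- something real follow-up scans never provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .transform import invert_field, warp_mask, warp_volume
from .volume import DeformationField, ImageVolume

__all__ = ["PhantomParams", "RegistrationPair", "generate_phantom", "sample_smooth_field", "make_registration_pair"]


@dataclass
class PhantomParams:
    """Parameters of one synthetic brain phantom."""

    shape: tuple[int, int, int] = (32, 32, 32)
    n_structures: int = 3
    lesion_radius_frac: float = 0.12
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ValueError("shape must be 3 integers, all >= 16")
        if not (0.0 < self.lesion_radius_frac <= 0.3):
            raise ValueError("lesion_radius_frac must be in (0, 0.3]")
        if not (0.0 <= self.noise_sd < 0.5):
            raise ValueError("noise_sd must be in [0, 0.5)")
        if self.n_structures < 0:
            raise ValueError("n_structures must be >= 0")


@dataclass
class RegistrationPair:
    """A fixed/moving volume pair with masks and (synthetic) true field.

    ``true_field`` is the displacement that registers moving onto fixed:
    warping ``moving`` by it reproduces ``fixed`` up to interpolation error
    and noise.  For real data it is ``None``.
    """

    fixed: ImageVolume
    moving: ImageVolume
    fixed_mask: ImageVolume
    moving_mask: ImageVolume
    true_field: DeformationField | None = None

    def __post_init__(self) -> None:
        if self.fixed.shape != self.moving.shape:
            raise ValueError("fixed and moving must have identical shape")
        for m in (self.fixed_mask, self.moving_mask):
            if not np.all(np.isin(np.unique(m.voxels), (0, 1))):
                raise ValueError("masks must be 0/1 volumes")
        if self.true_field is not None and self.true_field.spatial_shape != self.fixed.shape:
            raise ValueError("true_field shape must match the volumes")


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def generate_phantom(params: PhantomParams) -> tuple[ImageVolume, ImageVolume]:
    """Build one phantom volume and its brain mask, deterministic in the seed.

    Returns ``(volume, mask)``.  With ``n_structures=0`` and ``noise_sd=0``
    the volume is binary-valued (background 0, brain at one base intensity).
    """
    rng = np.random.default_rng(params.seed)
    shape = params.shape
    center = [s / 2.0 + rng.uniform(-0.03, 0.03) * s for s in shape]
    semi = [rng.uniform(0.33, 0.42) * s for s in shape]
    brain = _ellipsoid(shape, center, semi)

    lesion_radius = params.lesion_radius_frac * min(shape)
    if lesion_radius >= min(semi):
        raise ValueError("lesion larger than the brain region")

    vox = np.where(brain, 0.55, 0.0)
    for _ in range(params.n_structures):
        # structure centres stay well inside the brain ellipsoid
        offs = rng.uniform(-0.45, 0.45, size=3)
        c = [ci + o * si for ci, o, si in zip(center, offs, semi)]
        axes = rng.uniform(0.10, 0.22, size=3) * np.array(shape)
        intensity = rng.uniform(0.35, 1.0)
        region = _ellipsoid(shape, c, axes) & brain
        vox[region] = intensity

    if params.n_structures > 0:
        # a plain blob (n_structures=0) stays binary-valued; otherwise add
        # one low-intensity spherical lesion
        offs = rng.uniform(-0.35, 0.35, size=3)
        lc = [ci + o * si for ci, o, si in zip(center, offs, semi)]
        lesion = _ellipsoid(shape, lc, [lesion_radius] * 3) & brain
        vox[lesion] = 0.22

    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=shape)
        vox = np.where(brain, np.clip(vox + noise, 0.0, 1.0), 0.0)

    mask = brain.astype(np.uint8)
    return ImageVolume(vox), ImageVolume(mask)


def sample_smooth_field(
    shape: tuple[int, int, int],
    amplitude: float,
    smooth_sigma: float,
    seed: int,
) -> DeformationField:
    """Random smooth displacement field with a prescribed peak magnitude.

    Each component is Gaussian white noise convolved with a Gaussian kernel
    of sd ``smooth_sigma`` (voxels), rescaled so the maximum displacement
    magnitude equals ``amplitude`` (voxels), and forced to zero on a 2-voxel
    boundary shell so no sample ever maps outside the grid.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if smooth_sigma <= 0:
        raise ValueError("smooth_sigma must be > 0")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    disp = np.stack(
        [gaussian_filter(rng.standard_normal(shape), smooth_sigma) for _ in range(3)],
        axis=-1,
    )
    # zero displacement on the 2-voxel boundary shell, with a gradual taper
    # just inside so the field stays invertible (local Lipschitz < 1)
    for ax, s in enumerate(shape):
        ramp = np.ones(s)
        ramp[:2] = 0.0
        ramp[-2:] = 0.0
        taper = min(4, max(1, (s - 4) // 2))
        steps = np.linspace(0.0, 1.0, taper + 2)[1:-1]
        ramp[2 : 2 + taper] = steps
        ramp[-2 - taper : -2] = steps[::-1]
        sl = [None] * 3 + [None]
        sl[ax] = slice(None)
        disp *= ramp[tuple(sl)]
    if amplitude == 0:
        return DeformationField(np.zeros(shape + (3,)))
    mag = np.sqrt((disp**2).sum(axis=-1))
    peak = mag.max()
    if peak > 0:
        disp *= amplitude / peak
    return DeformationField(disp)


def make_registration_pair(
    params: PhantomParams,
    amplitude: float = 3.0,
    smooth_sigma: float = 6.0,
) -> RegistrationPair:
    """Generate a fixed/moving pair linked by a known smooth deformation.

    The fixed volume is a phantom; the moving volume is the fixed one warped
    by the (fixed-point) inverse of the sampled field, so that warping
    ``moving`` by the stored ``true_field`` recovers ``fixed`` up to
    interpolation error.
    """
    fixed, fixed_mask = generate_phantom(params)
    field = sample_smooth_field(params.shape, amplitude, smooth_sigma, seed=params.seed + 1)
    inverse = invert_field(field)
    moving = warp_volume(fixed, inverse, mode="trilinear")
    moving_mask = warp_mask(fixed_mask, inverse, method="nearest")
    return RegistrationPair(
        fixed=fixed,
        moving=moving,
        fixed_mask=fixed_mask,
        moving_mask=moving_mask,
        true_field=field,
    )
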