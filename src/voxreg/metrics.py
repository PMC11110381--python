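"""Registration quality metrics: Dice overlap, SSIM, endpoint error.

Dice is computed on 0/1 brain masks; SSIM follows the classic
luminance/contrast/structure formula with stabilising constants
C1 = (k1*L)^2, C2 = (k2*L)^2, evaluated over sliding uniform windows (7^3 by
default) and averaged over fully interior windows, with an optional single
global window.  Endpoint error compares a predicted displacement field with
the ground truth, which only synthetic pairs provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .volume import DeformationField, ImageVolume

__all__ = [
    "MetricsReport",
    "brain_mask_from_volume",
    "dice_score",
    "ssim_score",
    "mean_endpoint_error",
    "evaluate_registration",
]


@dataclass
class MetricsReport:
    """Metrics of one registration (endpoint error only for synthetic pairs)."""

    dice: float
    ssim: float
    sim_loss: float
    smooth_loss: float
    endpoint_error_mean: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.dice <= 1.0):
            raise ValueError(f"dice must lie in [0, 1], got {self.dice}")


def _vox(x) -> np.ndarray:
    return np.asarray(x.voxels if isinstance(x, ImageVolume) else x, dtype=np.float64)


def brain_mask_from_volume(vol, threshold: float = 0.0) -> np.ndarray:
    """0/1 mask of voxels with intensity strictly above ``threshold``."""
    return (_vox(vol) > threshold).astype(np.uint8)


def dice_score(a, b) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two 0/1 masks.

    Two empty masks score 1.0 by convention (the 0/0 limit of perfect
    agreement); empty vs non-empty scores 0.
    """
    av, bv = _vox(a), _vox(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch {av.shape} vs {bv.shape}")
    for v in (av, bv):
        if not np.all(np.isin(np.unique(v), (0, 1))):
            raise ValueError("dice_score requires binary 0/1 masks")
    denom = av.sum() + bv.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(av, bv).sum() / denom)


def ssim_score(
    x,
    y,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float = 1.0,
    window: int = 7,
    mode: str = "windowed",
) -> float:
    """Structural similarity index of two volumes.

    SSIM(x, y) = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
                 / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

    with maximum-likelihood (biased) variances/covariance.  ``windowed`` mode
    evaluates the formula over sliding uniform ``window^3`` boxes and averages
    over windows that fit entirely inside the volume; ``global`` mode treats
    the whole volume as a single window (the literal closed form).
    """
    xv, yv = _vox(x), _vox(y)
    if xv.shape != yv.shape:
        raise ValueError(f"shape mismatch {xv.shape} vs {yv.shape}")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    if mode == "global":
        mx, my = xv.mean(), yv.mean()
        vx, vy = xv.var(), yv.var()
        cov = ((xv - mx) * (yv - my)).mean()
        return float(
            (2 * mx * my + c1) * (2 * cov + c2) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        )
    if mode != "windowed":
        raise ValueError(f"unknown SSIM mode {mode!r}")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if any(s < window for s in xv.shape):
        raise ValueError(f"volume shape {xv.shape} smaller than window {window}")

    win = lambda v: uniform_filter(v, size=window)
    mx, my = win(xv), win(yv)
    vx = win(xv * xv) - mx * mx
    vy = win(yv * yv) - my * my
    cov = win(xv * yv) - mx * my
    ssim_map = (2 * mx * my + c1) * (2 * cov + c2) / (
        (mx * mx + my * my + c1) * (vx + vy + c2)
    )
    pad = window // 2
    interior = ssim_map[pad:-pad, pad:-pad, pad:-pad]
    return float(interior.mean())


def mean_endpoint_error(
    pred: DeformationField, truth: DeformationField, mask=None
) -> float:
    """Mean Euclidean distance (voxels) between predicted and true vectors."""
    if pred.spatial_shape != truth.spatial_shape:
        raise ValueError("fields must share a spatial shape")
    diff = pred.displacements.astype(np.float64) - truth.displacements.astype(np.float64)
    norms = np.sqrt((diff**2).sum(axis=-1))
    if mask is not None:
        mv = _vox(mask).astype(bool)
        if mv.shape != norms.shape:
            raise ValueError("mask shape must match the fields")
        if not mv.any():
            raise ValueError("mask selects no voxels")
        norms = norms[mv]
    return float(norms.mean())


def evaluate_registration(
    fixed,
    warped,
    field: DeformationField,
    fixed_mask=None,
    warped_mask=None,
    true_field: DeformationField | None = None,
    loss_config=None,
) -> MetricsReport:
    """Bundle Dice, SSIM, loss components, and (if available) endpoint error.

    Masks default to thresholding the volumes at 0, appropriate for
    skull-stripped data with an exactly-zero background.
    """
    from .losses import total_loss

    fm = brain_mask_from_volume(fixed) if fixed_mask is None else _vox(fixed_mask)
    wm = brain_mask_from_volume(warped) if warped_mask is None else _vox(warped_mask)
    comps = total_loss(fixed, warped, field, loss_config)
    epe = None
    if true_field is not None:
        epe = mean_endpoint_error(field, true_field)
    return MetricsReport(
        dice=dice_score(fm, wm),
        ssim=ssim_score(_vox(fixed), _vox(warped)),
        sim_loss=comps.similarity,
        smooth_loss=comps.smoothness,
        endpoint_error_mean=epe,
    )
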