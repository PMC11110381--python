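"""Unsupervised registration objective: Loss = -NCC + lambda * smoothness.

The data term is the local (windowed) squared normalized cross-correlation
between the fixed image and the warped moving image, computed over 9^3 boxes
by default; the regulariser is a diffusion penalty on the spatial forward
differences of the displacement field.  Both terms are reduced by means so
the regularisation weight lambda is resolution-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import nn
from .volume import DeformationField, ImageVolume

__all__ = ["LossConfig", "LossComponents", "local_ncc", "diffusion_regularizer", "total_loss"]


@dataclass
class LossConfig:
    """Configuration of the composite loss.

    lambda_reg
        Regularisation weight lambda >= 0 trading similarity against field
        smoothness (1 is the default; 0 disables regularisation).
    ncc_window
        Odd cubic window edge for local NCC (default 9).
    eps
        Stabiliser added symmetrically to the NCC numerator and denominator.
    """

    lambda_reg: float = 1.0
    ncc_window: int = 9
    eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.ncc_window < 3 or self.ncc_window % 2 == 0:
            raise ValueError("ncc_window must be odd and >= 3")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


class LossComponents(NamedTuple):
    total: float
    similarity: float  # L_sim = -local_ncc
    smoothness: float  # diffusion regulariser


def _vox(x) -> np.ndarray:
    return np.asarray(x.voxels if isinstance(x, ImageVolume) else x, dtype=np.float64)


def local_ncc(a, b, window: int = 9, eps: float = 1e-5) -> float:
    """Windowed squared cross-correlation similarity in [0, 1].

    For each voxel the squared correlation of the two images over the centred
    ``window^3`` box (zero-padded borders, full-size window everywhere) is

        cc = (sum (a-abar)(b-bbar))^2 + eps
             ------------------------------------------
             sum (a-abar)^2 * sum (b-bbar)^2 + eps

    and the returned value is the mean of cc over all voxels.  Identical or
    locally affine-related images score ~1; independent noise scores near
    1/window^3.  The data loss used in training is ``-local_ncc``.
    """
    av, bv = _vox(a), _vox(b)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    value, _ = nn.ncc_forward(av, bv, window=window, eps=eps)
    return value


def diffusion_regularizer(field: DeformationField) -> float:
    """Mean squared forward-difference of the displacement field.

    Squared forward differences of every component are summed per position
    along each axis, averaged over positions, and the three axis means are
    averaged.  Zero iff the field is constant; homogeneous of degree 2.
    """
    disp = np.asarray(field.displacements, dtype=np.float64)
    return nn.diffusion_forward(np.moveaxis(disp, -1, 0))


def total_loss(fixed, warped, field: DeformationField, cfg: LossConfig | None = None) -> LossComponents:
    """Composite unsupervised loss: ``-local_ncc + lambda * smoothness``."""
    if cfg is None:
        cfg = LossConfig()
    sim = -local_ncc(fixed, warped, window=cfg.ncc_window, eps=cfg.eps)
    smooth = diffusion_regularizer(field)
    return LossComponents(sim + cfg.lambda_reg * smooth, sim, smooth)
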