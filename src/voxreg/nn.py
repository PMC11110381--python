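"""Minimal NumPy building blocks for 3-D convolutional displacement networks.

Every primitive here provides a hand-derived reverse-mode gradient so the full
registration objective (local NCC data term + diffusion smoothness penalty)
can be minimised end to end with Adam.  Tensors are channels-first
``(C, X, Y, Z)`` float32; convolutions are 3x3x3 with padding 1 and stride 1
or 2, realised as 27 shifted channel-matmuls (fast under BLAS, light on
memory compared to im2col at 128^3).
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.ndimage import uniform_filter

DTYPE = np.float32

__all__ = [
    "Conv3d",
    "FlowNet",
    "Adam",
    "warp_forward",
    "warp_backward",
    "ncc_forward",
    "ncc_backward",
    "diffusion_forward",
    "diffusion_backward",
]


class Conv3d:
    """3x3x3 convolution, padding 1, stride 1 or 2, optional LeakyReLU fused off.

    He-style initialisation scaled for LeakyReLU; ``zero_init`` produces an
    all-zero layer (used for the flow head so training starts at the identity
    transform).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
        leaky_slope: float = 0.2,
        trainable: bool = True,
    ):
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        self.trainable = trainable
        if zero_init:
            self.w = np.zeros((c_out, c_in, 3, 3, 3), dtype=DTYPE)
        else:
            if rng is None:
                rng = np.random.default_rng(0)
            fan_in = c_in * 27
            std = np.sqrt(2.0 / ((1.0 + leaky_slope**2) * fan_in))
            self.w = rng.normal(0.0, std, size=(c_out, c_in, 3, 3, 3)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def zero_grad(self) -> None:
        self.gw.fill(0.0)
        self.gb.fill(0.0)

    def forward(self, x: np.ndarray):
        s = self.stride
        X, Y, Z = x.shape[1:]
        Xo, Yo, Zo = (X + s - 1) // s, (Y + s - 1) // s, (Z + s - 1) // s
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        out = np.empty((self.c_out, Xo, Yo, Zo), dtype=DTYPE)
        out[:] = self.b[:, None, None, None]
        acc = out.reshape(self.c_out, -1)
        for a, bb, c in product(range(3), repeat=3):
            xs = xp[:, a : a + s * Xo : s, bb : bb + s * Yo : s, c : c + s * Zo : s]
            acc += self.w[:, :, a, bb, c] @ xs.reshape(self.c_in, -1)
        return out, (xp, (Xo, Yo, Zo))

    def backward(self, gy: np.ndarray, cache):
        xp, (Xo, Yo, Zo) = cache
        s = self.stride
        gf = gy.reshape(self.c_out, -1)
        gxp = np.zeros_like(xp)
        for a, bb, c in product(range(3), repeat=3):
            sl = (
                slice(None),
                slice(a, a + s * Xo, s),
                slice(bb, bb + s * Yo, s),
                slice(c, c + s * Zo, s),
            )
            xs = xp[sl].reshape(self.c_in, -1)
            if self.trainable:
                self.gw[:, :, a, bb, c] += gf @ xs.T
            gxp[sl] += (self.w[:, :, a, bb, c].T @ gf).reshape(self.c_in, Xo, Yo, Zo)
        if self.trainable:
            self.gb += gy.sum(axis=(1, 2, 3))
        return gxp[:, 1:-1, 1:-1, 1:-1]


class FlowNet:
    """A declarative encoder-decoder executed by a tiny tape interpreter.

    ``steps`` is a list of ops applied in order to the running tensor:

    * ``("conv", i)``     -- apply ``convs[i]``;
    * ``("lrelu",)``      -- LeakyReLU with the network's negative slope;
    * ``("up",)``         -- 2x nearest-neighbour upsampling;
    * ``("save", name)``  -- remember the running tensor as a skip source;
    * ``("concat", name)``-- concatenate the saved tensor onto the channels.

    ``backward`` replays the tape in reverse, accumulating parameter gradients.
    """

    def __init__(self, steps, convs: list[Conv3d], leaky_slope: float = 0.2):
        self.steps = list(steps)
        self.convs = list(convs)
        self.leaky_slope = float(leaky_slope)
        self._tape = None

    # -- bookkeeping ---------------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(c.n_params for c in self.convs if c.trainable)

    def zero_grad(self) -> None:
        for c in self.convs:
            c.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        out = []
        for c in self.convs:
            out += [c.w, c.b]
        return out

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state) -> None:
        for dst, src in zip(self.state_arrays(), state):
            dst[...] = src

    # -- execution -----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        saved: dict[str, np.ndarray] = {}
        tape = []
        for step in self.steps:
            kind = step[0]
            if kind == "conv":
                layer = self.convs[step[1]]
                x, cache = layer.forward(x)
                tape.append(("conv", step[1], cache))
            elif kind == "lrelu":
                mask = x > 0
                x = np.where(mask, x, self.leaky_slope * x)
                tape.append(("lrelu", mask))
            elif kind == "up":
                tape.append(("up", x.shape))
                x = x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
            elif kind == "save":
                saved[step[1]] = x
                tape.append(("save", step[1]))
            elif kind == "concat":
                skip = saved[step[1]]
                tape.append(("concat", step[1], x.shape[0]))
                x = np.concatenate([x, skip], axis=0)
            else:  # pragma: no cover - builder bug
                raise ValueError(f"unknown step {kind!r}")
        self._tape = tape
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._tape is None:
            raise RuntimeError("backward called before forward")
        g = np.ascontiguousarray(g, dtype=DTYPE)
        skip_grads: dict[str, np.ndarray] = {}
        for entry in reversed(self._tape):
            kind = entry[0]
            if kind == "conv":
                g = self.convs[entry[1]].backward(g, entry[2])
            elif kind == "lrelu":
                mask = entry[1]
                g = np.where(mask, g, self.leaky_slope * g)
            elif kind == "up":
                c, X, Y, Z = entry[1]
                g = g.reshape(c, X, 2, Y, 2, Z, 2).sum(axis=(2, 4, 6))
            elif kind == "save":
                extra = skip_grads.pop(entry[1], None)
                if extra is not None:
                    g = g + extra
            elif kind == "concat":
                c_main = entry[2]
                name = entry[1]
                g_skip = g[c_main:]
                if name in skip_grads:
                    skip_grads[name] = skip_grads[name] + g_skip
                else:
                    skip_grads[name] = g_skip
                g = g[:c_main]
        self._tape = None
        return g


class Adam:
    """Adam optimiser over a FlowNet's convolution parameters."""

    def __init__(self, net: FlowNet, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self._layers = [c for c in net.convs if c.trainable]
        self._m = [
            (np.zeros_like(c.w), np.zeros_like(c.b)) for c in self._layers
        ]
        self._v = [
            (np.zeros_like(c.w), np.zeros_like(c.b)) for c in self._layers
        ]

    def step(self, grad_scale: float = 1.0) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for layer, (mw, mb), (vw, vb) in zip(self._layers, self._m, self._v):
            for p, g, m, v in ((layer.w, layer.gw, mw, vw), (layer.b, layer.gb, mb, vb)):
                g = g * grad_scale
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Differentiable trilinear warping
# ---------------------------------------------------------------------------

def warp_forward(vol: np.ndarray, disp: np.ndarray):
    """Trilinear sampling of ``vol`` at ``x + s(x)`` with border clamping.

    ``vol``: (X, Y, Z); ``disp``: (3, X, Y, Z) voxel-unit displacements.
    Returns the warped volume and a cache for :func:`warp_backward`.
    """
    X, Y, Z = vol.shape
    vol = np.ascontiguousarray(vol, dtype=DTYPE)
    idx = np.indices((X, Y, Z), dtype=DTYPE)
    p = idx + disp.astype(DTYPE)
    dims = np.array([X, Y, Z], dtype=DTYPE).reshape(3, 1, 1, 1)
    inb = (p >= 0) & (p <= dims - 1)  # clamp derivative mask, per axis
    pc = np.clip(p, 0, dims - 1)
    i0 = np.minimum(pc.astype(np.int64), (np.array([X, Y, Z]) - 2).reshape(3, 1, 1, 1))
    t = pc - i0

    flat = vol.ravel()
    base = (i0[0] * Y + i0[1]) * Z + i0[2]
    sx, sy, sz = Y * Z, Z, 1
    corners = {}
    for a, b, c in product((0, 1), repeat=3):
        corners[(a, b, c)] = flat[base + a * sx + b * sy + c * sz]

    tx, ty, tz = t
    ux, uy, uz = 1 - tx, 1 - ty, 1 - tz
    out = (
        corners[0, 0, 0] * ux * uy * uz
        + corners[1, 0, 0] * tx * uy * uz
        + corners[0, 1, 0] * ux * ty * uz
        + corners[0, 0, 1] * ux * uy * tz
        + corners[1, 1, 0] * tx * ty * uz
        + corners[1, 0, 1] * tx * uy * tz
        + corners[0, 1, 1] * ux * ty * tz
        + corners[1, 1, 1] * tx * ty * tz
    )
    return out, (corners, t, inb)


def warp_backward(gout: np.ndarray, cache) -> np.ndarray:
    """Gradient of the warped volume w.r.t. the displacement field."""
    corners, t, inb = cache
    tx, ty, tz = t
    ux, uy, uz = 1 - tx, 1 - ty, 1 - tz
    c = corners
    dpx = (
        (c[1, 0, 0] - c[0, 0, 0]) * uy * uz
        + (c[1, 1, 0] - c[0, 1, 0]) * ty * uz
        + (c[1, 0, 1] - c[0, 0, 1]) * uy * tz
        + (c[1, 1, 1] - c[0, 1, 1]) * ty * tz
    )
    dpy = (
        (c[0, 1, 0] - c[0, 0, 0]) * ux * uz
        + (c[1, 1, 0] - c[1, 0, 0]) * tx * uz
        + (c[0, 1, 1] - c[0, 0, 1]) * ux * tz
        + (c[1, 1, 1] - c[1, 0, 1]) * tx * tz
    )
    dpz = (
        (c[0, 0, 1] - c[0, 0, 0]) * ux * uy
        + (c[1, 0, 1] - c[1, 0, 0]) * tx * uy
        + (c[0, 1, 1] - c[0, 1, 0]) * ux * ty
        + (c[1, 1, 1] - c[1, 1, 0]) * tx * ty
    )
    g = np.stack([dpx, dpy, dpz]) * gout[None]
    return (g * inb).astype(DTYPE)


# ---------------------------------------------------------------------------
# Local (windowed) squared normalized cross-correlation
# ---------------------------------------------------------------------------

def _box_sums(v: np.ndarray, window: int) -> np.ndarray:
    """Sums over the centred window, truncated at the volume border."""
    n = window**3
    return uniform_filter(v, size=window, mode="constant", cval=0.0) * n


def _box_counts(shape, window: int) -> np.ndarray:
    """Per-voxel count of in-volume samples of the (truncated) window."""
    return _box_sums(np.ones(shape, dtype=np.float64), window)


def ncc_forward(a: np.ndarray, b: np.ndarray, window: int = 9, eps: float = 1e-5):
    """Mean over voxels of the squared local correlation coefficient.

    cc = (cross^2 + eps) / (var_a * var_b + eps), all moments over the
    centred ``window^3`` box truncated at the volume border (each voxel's
    statistics use only in-volume samples), which makes the score exactly
    invariant to affine intensity maps everywhere.  eps appears symmetrically
    so degenerate flat-vs-flat windows score 1 (perfectly matched) rather
    than blowing up or collapsing to 0; by Cauchy-Schwarz cc stays in [0, 1].
    Returns (value, cache) where the value is the similarity (higher = more
    similar); the data loss is its negative.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    n = np.maximum(_box_counts(a.shape, window), 1.0)
    sa, sb = _box_sums(a, window), _box_sums(b, window)
    sab = _box_sums(a * b, window)
    saa, sbb = _box_sums(a * a, window), _box_sums(b * b, window)
    cross = sab - sa * sb / n
    va = np.maximum(saa - sa * sa / n, 0.0)
    vb = np.maximum(sbb - sb * sb / n, 0.0)
    num = cross * cross + eps
    den = va * vb + eps
    cc = num / den
    value = float(cc.mean())
    cache = (a, b, sa, sb, cross, va, vb, num, den, window, n)
    return value, cache


def ncc_backward(cache) -> np.ndarray:
    """Gradient of :func:`ncc_forward`'s value w.r.t. its second argument."""
    a, b, sa, sb, cross, va, vb, num, den, window, n = cache
    g1 = 2.0 * cross / den  # d cc / d cross
    g2 = np.where(vb > 0, -num * va / (den * den), 0.0)  # d cc / d var_b
    term = _box_sums(g1, window) * a
    term += 2.0 * b * _box_sums(g2, window)
    term += _box_sums(-g1 * sa / n - 2.0 * g2 * sb / n, window)
    return (term / a.size).astype(DTYPE)


# ---------------------------------------------------------------------------
# Diffusion (first-difference) smoothness penalty
# ---------------------------------------------------------------------------

def diffusion_forward(disp: np.ndarray) -> float:
    """Mean squared forward difference of the field, averaged over the 3 axes.

    ``disp``: (3, X, Y, Z).  For each spatial axis the squared forward
    differences of all 3 components are summed per position and averaged over
    positions; the three axis means are then averaged.  A constant field
    scores 0; scaling the field by k scales the penalty by k^2.
    """
    total = 0.0
    for ax in range(3):
        d = np.diff(disp, axis=1 + ax)
        m = d.shape[1] * d.shape[2] * d.shape[3]  # positions per component
        total += float((d.astype(np.float64) ** 2).sum()) / m
    return total / 3.0


def diffusion_backward(disp: np.ndarray) -> np.ndarray:
    """Gradient of :func:`diffusion_forward` w.r.t. the field."""
    g = np.zeros_like(disp, dtype=DTYPE)
    for ax in range(3):
        d = np.diff(disp, axis=1 + ax)
        m = d.shape[1] * d.shape[2] * d.shape[3]
        coef = (2.0 / (3.0 * m)) * d
        sl_hi = [slice(None)] * 4
        sl_lo = [slice(None)] * 4
        sl_hi[1 + ax] = slice(1, None)
        sl_lo[1 + ax] = slice(None, -1)
        g[tuple(sl_hi)] += coef
        g[tuple(sl_lo)] -= coef
    return g
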