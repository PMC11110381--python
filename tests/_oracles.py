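"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity per voxel / per window with explicit
loops and direct formula arithmetic, sharing no code with the package's
vectorised implementations.
"""

import numpy as np


def brute_warp(vol, disp):
    """Per-voxel trilinear interpolation at x + s(x) with border clamping.

    vol: (X, Y, Z); disp: (X, Y, Z, 3). Returns the warped volume.
    """
    X, Y, Z = vol.shape
    out = np.empty_like(vol, dtype=np.float64)
    for i in range(X):
        for j in range(Y):
            for k in range(Z):
                px = min(max(i + disp[i, j, k, 0], 0.0), X - 1.0)
                py = min(max(j + disp[i, j, k, 1], 0.0), Y - 1.0)
                pz = min(max(k + disp[i, j, k, 2], 0.0), Z - 1.0)
                x0 = min(int(np.floor(px)), X - 2)
                y0 = min(int(np.floor(py)), Y - 2)
                z0 = min(int(np.floor(pz)), Z - 2)
                tx, ty, tz = px - x0, py - y0, pz - z0
                acc = 0.0
                for a in (0, 1):
                    for b in (0, 1):
                        for c in (0, 1):
                            w = (
                                (tx if a else 1 - tx)
                                * (ty if b else 1 - ty)
                                * (tz if c else 1 - tz)
                            )
                            acc += w * vol[x0 + a, y0 + b, z0 + c]
                out[i, j, k] = acc
    return out


def brute_local_ncc(a, b, window, eps):
    """Direct per-voxel windowed squared correlation, truncated windows."""
    X, Y, Z = a.shape
    r = window // 2
    total = 0.0
    for i in range(X):
        for j in range(Y):
            for k in range(Z):
                sl = (
                    slice(max(i - r, 0), min(i + r + 1, X)),
                    slice(max(j - r, 0), min(j + r + 1, Y)),
                    slice(max(k - r, 0), min(k + r + 1, Z)),
                )
                aw = a[sl].ravel()
                bw = b[sl].ravel()
                da = aw - aw.mean()
                db = bw - bw.mean()
                cross = float(da @ db)
                va = float(da @ da)
                vb = float(db @ db)
                total += (cross * cross + eps) / (va * vb + eps)
    return total / (X * Y * Z)


def brute_diffusion(disp4):
    """Axis-mean of summed squared forward differences; disp4: (X,Y,Z,3)."""
    axis_means = []
    for ax in range(3):
        sq_sum = 0.0
        count = 0
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        for comp in range(3):
            d = disp4[tuple(sl_hi) + (comp,)] - disp4[tuple(sl_lo) + (comp,)]
            sq_sum += float((d**2).sum())
        count = d.size  # positions per component along this axis
        axis_means.append(sq_sum / count)
    return sum(axis_means) / 3.0


def brute_ssim(x, y, k1=0.01, k2=0.03, data_range=1.0, window=7):
    """Mean of the SSIM formula over all fully interior windows."""
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    X, Y, Z = x.shape
    r = window // 2
    vals = []
    for i in range(r, X - r):
        for j in range(r, Y - r):
            for k in range(r, Z - r):
                sl = (
                    slice(i - r, i + r + 1),
                    slice(j - r, j + r + 1),
                    slice(k - r, k + r + 1),
                )
                xw, yw = x[sl].ravel(), y[sl].ravel()
                mx, my = xw.mean(), yw.mean()
                vx = ((xw - mx) ** 2).mean()
                vy = ((yw - my) ** 2).mean()
                cov = ((xw - mx) * (yw - my)).mean()
                vals.append(
                    (2 * mx * my + c1)
                    * (2 * cov + c2)
                    / ((mx**2 + my**2 + c1) * (vx + vy + c2))
                )
    return float(np.mean(vals))


def conv3d_param_count(filter_pairs):
    """Closed-form parameter arithmetic: sum of 27*c_in*c_out + c_out."""
    return sum(27 * ci * co + co for ci, co in filter_pairs)
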