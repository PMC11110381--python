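"""Gradient correctness of the hand-derived reverse-mode primitives.

Every backward pass is checked against central finite differences; these are
the foundations the whole training loop rests on.
"""

import numpy as np
import pytest

from voxreg import nn


class TestConvGradients:
    def test_input_gradient_matches_finite_differences(self, rng):
        conv = nn.Conv3d(2, 3, stride=2, rng=rng)
        x = rng.random((2, 8, 8, 8)).astype(np.float32)
        y, cache = conv.forward(x)
        g = rng.random(y.shape).astype(np.float32)
        gx = conv.backward(g, cache)
        h = 1e-3
        for _ in range(8):
            c = (rng.integers(2),) + tuple(rng.integers(0, 8, 3))
            x2, x3 = x.copy(), x.copy()
            x2[c] += h
            x3[c] -= h
            num = float(((conv.forward(x2)[0] - conv.forward(x3)[0]) * g).sum()) / (2 * h)
            assert num == pytest.approx(float(gx[c]), abs=5e-4)

    def test_weight_gradient_matches_finite_differences(self, rng):
        conv = nn.Conv3d(2, 2, stride=1, rng=rng)
        x = rng.random((2, 6, 6, 6)).astype(np.float32)
        y, cache = conv.forward(x)
        g = rng.random(y.shape).astype(np.float32)
        conv.backward(g, cache)
        h = 1e-3
        for _ in range(8):
            c = tuple(rng.integers(s) for s in conv.w.shape)
            w0 = conv.w[c]
            conv.w[c] = w0 + h
            y2, _ = conv.forward(x)
            conv.w[c] = w0 - h
            y3, _ = conv.forward(x)
            conv.w[c] = w0
            num = float(((y2 - y3) * g).sum()) / (2 * h)
            assert num == pytest.approx(float(conv.gw[c]), abs=1e-3)

    def test_stride_two_halves_resolution(self, rng):
        conv = nn.Conv3d(1, 1, stride=2, rng=rng)
        y, _ = conv.forward(rng.random((1, 16, 16, 16)).astype(np.float32))
        assert y.shape == (1, 8, 8, 8)


class TestWarpGradient:
    def test_matches_finite_differences(self, rng):
        vol = rng.random((6, 6, 6))
        disp = rng.normal(0, 0.8, (3, 6, 6, 6)).astype(np.float32)
        out, cache = nn.warp_forward(vol, disp)
        g = rng.random(out.shape)
        gd = nn.warp_backward(g, cache)
        h = 1e-4
        for _ in range(15):
            c = (rng.integers(3),) + tuple(rng.integers(1, 5, 3))
            d2, d3 = disp.copy(), disp.copy()
            d2[c] += h
            d3[c] -= h
            num = float(((nn.warp_forward(vol, d2)[0] - nn.warp_forward(vol, d3)[0]) * g).sum()) / (2 * h)
            assert num == pytest.approx(float(gd[c]), abs=2e-3)

    def test_agrees_with_public_warp(self, rng):
        # the differentiable sampler and the scipy-based public path coincide
        from voxreg import DeformationField, warp_volume

        vol = rng.random((8, 8, 8))
        disp4 = rng.normal(0, 1.5, (8, 8, 8, 3))
        out, _ = nn.warp_forward(vol, np.moveaxis(disp4, -1, 0))
        ref = warp_volume(vol, DeformationField(disp4))
        np.testing.assert_allclose(out, ref, atol=1e-5)


class TestLossGradients:
    def test_ncc_gradient_matches_finite_differences(self, rng):
        a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        _, cache = nn.ncc_forward(a, b, 5, 1e-5)
        gb = nn.ncc_backward(cache)
        for _ in range(15):
            c = tuple(rng.integers(0, 8, 3))
            b2, b3 = b.copy(), b.copy()
            b2[c] += 1e-6
            b3[c] -= 1e-6
            num = (nn.ncc_forward(a, b2, 5, 1e-5)[0] - nn.ncc_forward(a, b3, 5, 1e-5)[0]) / 2e-6
            assert num == pytest.approx(float(gb[c]), abs=1e-7)

    def test_diffusion_gradient_matches_finite_differences(self, rng):
        d = rng.normal(0, 1, (3, 6, 6, 6))
        gd = nn.diffusion_backward(d)
        for _ in range(15):
            c = (rng.integers(3),) + tuple(rng.integers(0, 6, 3))
            d2, d3 = d.copy(), d.copy()
            d2[c] += 1e-6
            d3[c] -= 1e-6
            num = (nn.diffusion_forward(d2) - nn.diffusion_forward(d3)) / 2e-6
            assert num == pytest.approx(float(gd[c]), abs=1e-7)


class TestFlowNetTape:
    def test_skip_concat_backward_shapes(self, rng):
        convs = [nn.Conv3d(1, 2, stride=2, rng=rng), nn.Conv3d(3, 1, stride=1, rng=rng)]
        steps = [
            ("save", "in"),
            ("conv", 0),
            ("lrelu",),
            ("up",),
            ("concat", "in"),
            ("conv", 1),
        ]
        net = nn.FlowNet(steps, convs)
        x = rng.random((1, 8, 8, 8)).astype(np.float32)
        y = net.forward(x)
        assert y.shape == (1, 8, 8, 8)
        gx = net.backward(np.ones_like(y))
        assert gx.shape == x.shape

    def test_backward_without_forward_raises(self, rng):
        net = nn.FlowNet([], [])
        with pytest.raises(RuntimeError):
            net.backward(np.zeros((1, 4, 4, 4), np.float32))

    def test_adam_moves_parameters_toward_lower_loss(self, rng):
        # 1-layer net, quadratic target: a few Adam steps must reduce loss
        conv = nn.Conv3d(1, 1, stride=1, rng=rng)
        net = nn.FlowNet([("conv", 0)], [conv])
        adam = nn.Adam(net, lr=1e-2)
        x = rng.random((1, 6, 6, 6)).astype(np.float32)
        target = rng.random((1, 6, 6, 6)).astype(np.float32)
        losses = []
        for _ in range(30):
            y = net.forward(x)
            losses.append(float(((y - target) ** 2).mean()))
            net.zero_grad()
            net.backward(2 * (y - target) / y.size)
            adam.step()
        assert losses[-1] < losses[0] * 0.9
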