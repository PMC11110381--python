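"""Displacement-prediction network builders.

Three fully convolutional encoder-decoder variants map a 2-channel volume
(the concatenated fixed and moving images) to a 3-channel displacement field
at the input resolution:

* ``convunet_dir`` -- 4 stride-2 encoder convs, a 2-conv bottleneck, 4
  upsample+skip decoder levels, 3 extra convs, and a linear flow head;
* ``vm1`` / ``vm2`` -- the two classic VoxelMorph baselines (parameter counts
  259,675 and 300,547).

All convolutions are 3x3x3 with LeakyReLU hidden activations; upsampling is
2x nearest-neighbour followed by a stride-1 convolution, with skip tensors
concatenated before the convolution.  The flow head is zero-initialised so an
untrained network predicts the identity transform.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Conv3d, FlowNet
from .volume import DeformationField

__all__ = [
    "NetworkConfig",
    "RegistrationNetwork",
    "build_convunet_dir",
    "build_voxelmorph",
    "build_network",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("convunet_dir", "vm1", "vm2")


@dataclass
class NetworkConfig:
    """Declarative description of a displacement network.

    The filter lists apply to the ``convunet_dir`` variant; the VoxelMorph
    baselines have their filter counts fixed by their published topologies.
    """

    variant: str = "convunet_dir"
    input_shape: tuple[int, int, int] = (128, 128, 128)
    enc_filters: tuple[int, ...] = (16, 32, 32, 32)
    bottleneck_filters: tuple[int, ...] = (32, 32)
    dec_filters: tuple[int, ...] = (32, 32, 32, 32)
    extra_filters: tuple[int, ...] = (16, 16, 16)
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        self.input_shape = tuple(int(s) for s in self.input_shape)
        if len(self.enc_filters) != 4:
            raise ValueError("enc_filters must list 4 downsampling levels")
        if any(s % 16 != 0 or s <= 0 for s in self.input_shape):
            raise ValueError(
                f"input_shape must be divisible by 16 (4 halvings), got {self.input_shape}"
            )


class RegistrationNetwork:
    """A parameterised map (fixed, moving) -> displacement field."""

    def __init__(self, net: FlowNet, config: NetworkConfig):
        self.net = net
        self.config = config

    @property
    def parameter_count(self) -> int:
        return self.net.n_params

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return self.config.input_shape

    def _check_shape(self, shape) -> None:
        if tuple(shape) != self.input_shape:
            raise ValueError(
                f"volume shape {tuple(shape)} does not match network input {self.input_shape}"
            )

    def forward_channels(self, x: np.ndarray) -> np.ndarray:
        """Raw forward pass: (2, X, Y, Z) -> (3, X, Y, Z)."""
        return self.net.forward(x)

    def predict_field(self, fixed, moving) -> DeformationField:
        """Predict the displacement registering ``moving`` onto ``fixed``."""
        fv = np.asarray(getattr(fixed, "voxels", fixed), dtype=np.float32)
        mv = np.asarray(getattr(moving, "voxels", moving), dtype=np.float32)
        self._check_shape(fv.shape)
        self._check_shape(mv.shape)
        out = self.net.forward(np.stack([fv, mv]))
        return DeformationField(np.moveaxis(out.astype(np.float64), 0, -1))


def _conv(convs, steps, c_in, c_out, stride, rng, slope, activate=True, zero_init=False):
    convs.append(Conv3d(c_in, c_out, stride=stride, rng=rng, zero_init=zero_init, leaky_slope=slope))
    steps.append(("conv", len(convs) - 1))
    if activate:
        steps.append(("lrelu",))
    return c_out


def build_convunet_dir(cfg: NetworkConfig) -> RegistrationNetwork:
    """U-Net style variant: strided encoder, bottleneck, skip decoder, extras."""
    if cfg.variant != "convunet_dir":
        raise ValueError("config variant must be 'convunet_dir'")
    rng = np.random.default_rng(cfg.seed)
    convs: list[Conv3d] = []
    steps: list[tuple] = [("save", "x0")]
    c = 2
    skip_channels = []
    for i, f in enumerate(cfg.enc_filters):
        c = _conv(convs, steps, c, f, 2, rng, cfg.leaky_slope)
        if i < 3:
            skip_channels.append(c)
            steps.append(("save", f"x{i + 1}"))
    for f in cfg.bottleneck_filters:
        c = _conv(convs, steps, c, f, 1, rng, cfg.leaky_slope)
    skips = ["x3", "x2", "x1", "x0"]
    skip_c = [skip_channels[2], skip_channels[1], skip_channels[0], 2]
    for f, name, sc in zip(cfg.dec_filters, skips, skip_c):
        steps.append(("up",))
        steps.append(("concat", name))
        c = _conv(convs, steps, c + sc, f, 1, rng, cfg.leaky_slope)
    for f in cfg.extra_filters:
        c = _conv(convs, steps, c, f, 1, rng, cfg.leaky_slope)
    _conv(convs, steps, c, 3, 1, rng, cfg.leaky_slope, activate=False, zero_init=True)
    return RegistrationNetwork(FlowNet(steps, convs, cfg.leaky_slope), cfg)


def build_voxelmorph(variant: str, input_shape=(128, 128, 128), seed: int = 0) -> RegistrationNetwork:
    """Build the VM1 or VM2 baseline at the given input shape.

    Both share a (16, 32, 32, 32) stride-2 encoder.  VM1's decoder uses
    filters (32, 32, 32, 32, 8, 8); VM2's uses (32, 32, 32, 32, 32, 16, 16)
    with an extra half-resolution convolution.  Skip tensors (and finally the
    2-channel input itself) are concatenated before each decoder convolution.
    """
    if variant not in ("vm1", "vm2"):
        raise ValueError(f"unknown VoxelMorph variant {variant!r}")
    cfg = NetworkConfig(variant=variant, input_shape=tuple(input_shape), seed=seed)
    rng = np.random.default_rng(seed)
    slope = cfg.leaky_slope
    convs: list[Conv3d] = []
    steps: list[tuple] = [("save", "x0")]
    c = 2
    for i, f in enumerate((16, 32, 32, 32)):
        c = _conv(convs, steps, c, f, 2, rng, slope)
        if i < 3:
            steps.append(("save", f"x{i + 1}"))
    # decoder at 1/16 resolution
    c = _conv(convs, steps, c, 32, 1, rng, slope)
    for name, sc in (("x3", 32), ("x2", 32), ("x1", 16)):
        steps.append(("up",))
        steps.append(("concat", name))
        c = _conv(convs, steps, c + sc, 32, 1, rng, slope)
    if variant == "vm1":
        c = _conv(convs, steps, c, 8, 1, rng, slope)  # half resolution
        steps.append(("up",))
        steps.append(("concat", "x0"))
        c = _conv(convs, steps, c + 2, 8, 1, rng, slope)
    else:
        c = _conv(convs, steps, c, 32, 1, rng, slope)  # half resolution
        steps.append(("up",))
        steps.append(("concat", "x0"))
        c = _conv(convs, steps, c + 2, 16, 1, rng, slope)
        c = _conv(convs, steps, c, 16, 1, rng, slope)
    _conv(convs, steps, c, 3, 1, rng, slope, activate=False, zero_init=True)
    return RegistrationNetwork(FlowNet(steps, convs, slope), cfg)


def build_network(cfg: NetworkConfig) -> RegistrationNetwork:
    """Dispatch on ``cfg.variant``."""
    if cfg.variant == "convunet_dir":
        return build_convunet_dir(cfg)
    return build_voxelmorph(cfg.variant, cfg.input_shape, seed=cfg.seed)


def count_parameters(net: RegistrationNetwork) -> int:
    """Total trainable weights and biases."""
    return net.net.n_params


def save_checkpoint(net: RegistrationNetwork, path: str | Path, extra: dict | None = None) -> None:
    """Save weights as .npz with a JSON sidecar recording config (+ extras)."""
    path = Path(path)
    arrays = {f"arr_{i}": a for i, a in enumerate(net.net.state_arrays())}
    np.savez(path, **arrays)
    sidecar = {"config": asdict(net.config)}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> RegistrationNetwork:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = sidecar["config"]
    for key in ("input_shape", "enc_filters", "bottleneck_filters", "dec_filters", "extra_filters"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = NetworkConfig(**cfg_d)
    net = build_network(cfg)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        state = [data[f"arr_{i}"] for i in range(len(data.files))]
    net.net.set_state(state)
    return net
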