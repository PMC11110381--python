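"""High-level modelling interface: a Model fitted to data, yielding Results.

``DeformableRegistration`` holds the registration pairs and the architecture
/ loss configuration; ``fit()`` runs the unsupervised training loop and
returns a ``RegistrationResults`` object carrying the trained network, the
per-epoch loss history, and evaluation helpers, with a ``summary()`` text
table in the style of classical statistical modelling packages.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .losses import LossConfig
from .metrics import evaluate_registration
from .networks import NetworkConfig, RegistrationNetwork, build_network, count_parameters
from .phantom import PhantomParams, RegistrationPair, make_registration_pair
from .training import TrainConfig, register_pair, train_model
from .volume import DeformationField, ImageVolume

__all__ = ["DeformableRegistration", "RegistrationResults"]


class DeformableRegistration:
    """Unsupervised deformable-registration model over a set of image pairs.

    Parameters
    ----------
    train_pairs, val_pairs
        :class:`RegistrationPair` lists; all volumes must share one shape,
        divisible by 16 (four resolution halvings).
    variant
        ``"convunet_dir"`` (default), ``"vm1"`` or ``"vm2"``.
    network_config
        Full architecture override; built from ``variant`` + data shape when
        omitted.
    loss_config
        Similarity window / regularisation weight; defaults to lambda=1,
        window 9^3.
    """

    def __init__(
        self,
        train_pairs: list[RegistrationPair],
        val_pairs: list[RegistrationPair] | None = None,
        variant: str = "convunet_dir",
        network_config: NetworkConfig | None = None,
        loss_config: LossConfig | None = None,
    ):
        self.train_pairs = list(train_pairs)
        self.val_pairs = list(val_pairs or [])
        if not self.train_pairs:
            raise ValueError("at least one training pair is required")
        shapes = {p.fixed.shape for p in self.train_pairs + self.val_pairs}
        if len(shapes) > 1:
            raise ValueError(f"all pairs must share one shape, got {shapes}")
        self.input_shape = next(iter(shapes))
        if network_config is None:
            network_config = NetworkConfig(variant=variant, input_shape=self.input_shape)
        self.network_config = network_config
        self.loss_config = loss_config or LossConfig()

    @classmethod
    def from_synthetic(
        cls,
        n_pairs: int = 8,
        n_val: int = 0,
        shape: tuple[int, int, int] = (32, 32, 32),
        amplitude: float = 3.0,
        smooth_sigma: float = 6.0,
        noise_sd: float = 0.02,
        seed: int = 0,
        **kwargs,
    ) -> "DeformableRegistration":
        """Build a model over freshly generated synthetic phantom pairs."""
        pairs = [
            make_registration_pair(
                PhantomParams(shape=shape, noise_sd=noise_sd, seed=seed + 100 * i),
                amplitude=amplitude,
                smooth_sigma=smooth_sigma,
            )
            for i in range(n_pairs + n_val)
        ]
        return cls(pairs[:n_pairs], pairs[n_pairs:], **kwargs)

    def fit(
        self,
        epochs: int = 150,
        learning_rate: float = 1e-4,
        batch_size: int = 1,
        seed: int = 0,
        checkpoint_dir: str | Path | None = None,
        verbose: bool = False,
    ) -> "RegistrationResults":
        """Train the displacement network; returns a Results object."""
        cfg = TrainConfig(
            learning_rate=learning_rate,
            epochs=epochs,
            batch_size=batch_size,
            lambda_reg=self.loss_config.lambda_reg,
            seed=seed,
            checkpoint_dir=checkpoint_dir,
            ncc_window=self.loss_config.ncc_window,
            eps=self.loss_config.eps,
        )
        net_cfg = self.network_config
        if net_cfg.seed != seed:
            net_cfg = NetworkConfig(**{**net_cfg.__dict__, "seed": seed})
        net = build_network(net_cfg)
        net, history = train_model(net, self.train_pairs, self.val_pairs, cfg, verbose=verbose)
        return RegistrationResults(self, net, history, cfg)


class RegistrationResults:
    """Fitted registration model: trained weights, history, diagnostics."""

    def __init__(
        self,
        model: DeformableRegistration,
        network: RegistrationNetwork,
        history: list[dict],
        train_config: TrainConfig,
    ):
        self.model = model
        self.network = network
        self.history = pd.DataFrame(
            history, columns=["epoch", "train_sim", "train_smooth", "train_total", "val_total"]
        )
        self.train_config = train_config

    # -- inference -----------------------------------------------------------
    def register(
        self, fixed: ImageVolume, moving: ImageVolume
    ) -> tuple[ImageVolume, DeformationField]:
        """Warp ``moving`` onto ``fixed``; returns (warped, field)."""
        return register_pair(self.network, fixed, moving)

    def evaluate(self, pairs: list[RegistrationPair]) -> pd.DataFrame:
        """Per-pair Dice/SSIM/loss/endpoint-error table after registration."""
        from .transform import warp_mask

        rows = []
        for i, pair in enumerate(pairs):
            warped, field = self.register(pair.fixed, pair.moving)
            warped_mask = warp_mask(pair.moving_mask, field)
            report = evaluate_registration(
                pair.fixed,
                warped,
                field,
                fixed_mask=pair.fixed_mask,
                warped_mask=warped_mask,
                true_field=pair.true_field,
                loss_config=self.model.loss_config,
            )
            rows.append(
                {
                    "pair": i,
                    "dice": report.dice,
                    "ssim": report.ssim,
                    "sim_loss": report.sim_loss,
                    "smooth_loss": report.smooth_loss,
                    "epe_mean": report.endpoint_error_mean,
                }
            )
        return pd.DataFrame(rows)

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text fit summary in the classical-results-table style."""
        cfg = self.model.network_config
        tc = self.train_config
        lines = [
            "Deformable Registration Results",
            "=" * 46,
            f"{'Variant:':<26}{cfg.variant}",
            f"{'Input shape:':<26}{cfg.input_shape}",
            f"{'Trainable parameters:':<26}{count_parameters(self.network):,}",
            f"{'Training pairs:':<26}{len(self.model.train_pairs)}",
            f"{'Validation pairs:':<26}{len(self.model.val_pairs)}",
            f"{'Epochs:':<26}{tc.epochs}",
            f"{'Learning rate (Adam):':<26}{tc.learning_rate:g}",
            f"{'Batch size:':<26}{tc.batch_size}",
            f"{'lambda (smoothness):':<26}{tc.lambda_reg:g}",
            f"{'NCC window:':<26}{tc.ncc_window}^3",
            f"{'Seed:':<26}{tc.seed}",
        ]
        if len(self.history):
            first = self.history.iloc[0]
            last = self.history.iloc[-1]
            lines += [
                "-" * 46,
                f"{'First-epoch train loss:':<26}{first.train_total:+.4f}",
                f"{'Final-epoch train loss:':<26}{last.train_total:+.4f}",
            ]
            if np.isfinite(last.val_total):
                best = self.history.loc[self.history.val_total.idxmin()]
                lines += [
                    f"{'Final validation loss:':<26}{last.val_total:+.4f}",
                    f"{'Best validation epoch:':<26}{int(best.epoch)}",
                ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n = len(self.history)
        return f"<RegistrationResults: {self.model.network_config.variant}, {n} epochs>"
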