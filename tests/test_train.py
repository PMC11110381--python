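import numpy as np
import pytest

from voxreg import (
    DeformableRegistration,
    LossConfig,
    NetworkConfig,
    PhantomParams,
    TrainConfig,
    build_network,
    make_registration_pair,
    register_pair,
    train_model,
)


def tiny_pairs(n, seed=0, shape=(16, 16, 16), amplitude=1.5):
    return [
        make_registration_pair(
            PhantomParams(shape=shape, seed=seed + 10 * i), amplitude=amplitude, smooth_sigma=4.0
        )
        for i in range(n)
    ]


class TestTrainModel:
    def test_zero_epochs_returns_untouched_network_and_empty_history(self):
        pairs = tiny_pairs(2)
        net = build_network(NetworkConfig(input_shape=(16, 16, 16)))
        before = [a.copy() for a in net.net.state_arrays()]
        net2, history = train_model(net, pairs, [], TrainConfig(epochs=0))
        assert history == []
        assert net2 is net
        for a, b in zip(net.net.state_arrays(), before):
            np.testing.assert_array_equal(a, b)

    def test_short_run_reduces_training_loss(self):
        pairs = tiny_pairs(3, seed=5)
        net = build_network(NetworkConfig(input_shape=(16, 16, 16), seed=1))
        _, history = train_model(net, pairs, [], TrainConfig(epochs=8, seed=1))
        assert len(history) == 8
        assert history[-1]["train_total"] < history[0]["train_total"]

    def test_history_reproducible_under_fixed_seed(self):
        cfg = TrainConfig(epochs=3, seed=9)
        h = []
        for _ in range(2):
            pairs = tiny_pairs(2, seed=3)
            net = build_network(NetworkConfig(input_shape=(16, 16, 16), seed=9))
            _, hist = train_model(net, pairs, [], cfg)
            h.append([row["train_total"] for row in hist])
        assert h[0] == h[1]

    def test_mismatched_pair_shapes_rejected(self):
        pairs = tiny_pairs(1, shape=(16, 16, 16)) + tiny_pairs(1, shape=(32, 32, 32))
        net = build_network(NetworkConfig(input_shape=(16, 16, 16)))
        with pytest.raises(ValueError, match="shape"):
            train_model(net, pairs, [], TrainConfig(epochs=1))

    def test_best_validation_checkpoint_written(self, tmp_path):
        pairs = tiny_pairs(3, seed=2)
        net = build_network(NetworkConfig(input_shape=(16, 16, 16), seed=2))
        _, hist = train_model(
            net, pairs[:2], pairs[2:], TrainConfig(epochs=3, seed=2, checkpoint_dir=tmp_path)
        )
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "best.json").exists()
        assert (tmp_path / "final.npz").exists()
        assert all(np.isfinite(row["val_total"]) for row in hist)


class TestRegisterPair:
    def test_zero_initialized_net_returns_moving_unchanged(self):
        pair = tiny_pairs(1, seed=4)[0]
        net = build_network(NetworkConfig(input_shape=(16, 16, 16)))
        warped, field = register_pair(net, pair.fixed, pair.moving)
        np.testing.assert_array_equal(warped.voxels, pair.moving.voxels)
        assert np.all(field.displacements == 0)

    def test_field_shape_contract(self):
        pair = tiny_pairs(1)[0]
        net = build_network(NetworkConfig(input_shape=(16, 16, 16)))
        _, field = register_pair(net, pair.fixed, pair.moving)
        assert field.displacements.shape == (16, 16, 16, 3)

    def test_inference_does_not_mutate_weights(self):
        pair = tiny_pairs(1)[0]
        net = build_network(NetworkConfig(input_shape=(16, 16, 16), seed=5))
        checksums = [a.copy() for a in net.net.state_arrays()]
        register_pair(net, pair.fixed, pair.moving)
        for a, b in zip(net.net.state_arrays(), checksums):
            np.testing.assert_array_equal(a, b)

    def test_wrong_shape_rejected(self, rng):
        net = build_network(NetworkConfig(input_shape=(16, 16, 16)))
        from voxreg import ImageVolume

        big = ImageVolume(rng.random((32, 32, 32)))
        with pytest.raises(ValueError):
            net.predict_field(big, big)


class TestModelResultsSurface:
    def test_fit_returns_results_with_history_and_summary(self):
        model = DeformableRegistration.from_synthetic(
            n_pairs=2, n_val=1, shape=(16, 16, 16), amplitude=1.5, seed=3,
            loss_config=LossConfig(lambda_reg=1.0),
        )
        res = model.fit(epochs=2, seed=3)
        assert list(res.history.columns) == [
            "epoch", "train_sim", "train_smooth", "train_total", "val_total",
        ]
        assert len(res.history) == 2
        text = res.summary()
        assert "convunet_dir" in text
        assert "Trainable parameters" in text

    def test_evaluate_reports_all_metric_columns(self):
        model = DeformableRegistration.from_synthetic(
            n_pairs=2, shape=(16, 16, 16), amplitude=1.5, seed=6
        )
        res = model.fit(epochs=1, seed=6)
        df = res.evaluate(model.train_pairs)
        assert set(df.columns) == {"pair", "dice", "ssim", "sim_loss", "smooth_loss", "epe_mean"}
        assert np.isfinite(df[["dice", "ssim", "sim_loss", "smooth_loss", "epe_mean"]]).all().all()

    def test_inconsistent_shapes_rejected(self):
        pairs = tiny_pairs(1, shape=(16, 16, 16)) + tiny_pairs(1, shape=(32, 32, 32))
        with pytest.raises(ValueError, match="shape"):
            DeformableRegistration(pairs)
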