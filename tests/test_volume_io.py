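import numpy as np
import pytest
from hypothesis import given, strategies as st

from voxreg import ImageVolume, load_volume, preprocess_volume, save_volume, split_dataset
from voxreg.volume_io import read_split_manifest, write_split_manifest


class TestNiftiRoundTrip:
    def test_zero_volume_reads_back(self, tmp_path):
        path = tmp_path / "zeros.nii.gz"
        save_volume(ImageVolume(np.zeros((4, 4, 4))), path)
        vol = load_volume(path)
        assert vol.shape == (4, 4, 4)
        assert np.all(vol.voxels == 0)
        assert vol.spacing == (1.0, 1.0, 1.0)

    def test_random_volume_round_trips_bit_exactly(self, tmp_path, rng):
        vox = rng.random((8, 8, 8))
        save_volume(ImageVolume(vox, spacing=(1.0, 1.5, 2.0)), tmp_path / "r.nii")
        back = load_volume(tmp_path / "r.nii")
        np.testing.assert_array_equal(back.voxels, vox)
        assert back.spacing == pytest.approx((1.0, 1.5, 2.0))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "absent.nii.gz")

    def test_non_3d_image_raises(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((5, 5)), np.eye(4)), str(tmp_path / "flat.nii"))
        with pytest.raises(ValueError, match="3-D"):
            load_volume(tmp_path / "flat.nii")

    def test_nan_volume_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ImageVolume(np.full((4, 4, 4), np.nan))


class TestPreprocess:
    def test_full_pipeline_shape(self, rng):
        vox = np.zeros((240, 240, 155))
        vox[40:200, 50:190, 20:130] = rng.random((160, 140, 110)) + 0.1
        out = preprocess_volume(ImageVolume(vox), (224, 224, 155), (128, 128, 128))
        assert out.shape == (128, 128, 128)
        assert out.voxels.min() == 0.0
        assert out.voxels.max() == 1.0

    def test_normalization_range_without_resampling(self, rng):
        vox = rng.random((16, 16, 16))
        out = preprocess_volume(ImageVolume(vox), (16, 16, 16), (16, 16, 16))
        assert out.voxels.min() == 0.0
        assert out.voxels.max() == 1.0

    def test_linear_ramp_matches_closed_form(self):
        # z-score then min-max of a ramp is the ramp rescaled to [0, 1]
        ramp = np.broadcast_to(np.arange(8.0)[:, None, None], (8, 8, 8)).copy()
        out = preprocess_volume(ImageVolume(ramp), (8, 8, 8), (8, 8, 8))
        z = (ramp - ramp.mean()) / ramp.std()
        expected = (z - z.min()) / (z.max() - z.min())
        np.testing.assert_allclose(out.voxels, expected, atol=1e-12)

    def test_crop_exceeding_input_raises(self):
        with pytest.raises(ValueError, match="crop"):
            preprocess_volume(ImageVolume(np.zeros((8, 8, 8))), (16, 8, 8), (8, 8, 8))

    def test_constant_input_maps_to_zeros(self):
        out = preprocess_volume(ImageVolume(np.full((8, 8, 8), 3.0)), (8, 8, 8), (4, 4, 4))
        assert np.all(out.voxels == 0)

    def test_crop_centers_on_content(self, rng):
        vox = np.zeros((32, 32, 32))
        vox[20:28, 20:28, 20:28] = 0.5 + 0.5 * rng.random((8, 8, 8))  # off-centre
        out = preprocess_volume(ImageVolume(vox), (8, 8, 8), (8, 8, 8))
        # the centred crop captures the content cube: nothing left at zero
        assert (out.voxels > 0).sum() == 8**3 - 1  # only the min voxel maps to 0


class TestSplitDataset:
    def test_study_sizes_102_26_32(self):
        ids = [f"s{i}" for i in range(160)]
        for seed in (0, 1, 99):
            s = split_dataset(ids, (0.64, 0.16, 0.20), seed)
            assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (102, 26, 32)

    def test_degenerate_all_train(self):
        s = split_dataset(list("abcdefghij"), (1.0, 0.0, 0.0), 3)
        assert sorted(s.train_ids) == sorted("abcdefghij")
        assert s.val_ids == [] and s.test_ids == []

    def test_deterministic_and_seed_sensitive(self):
        ids = [f"s{i}" for i in range(50)]
        a = split_dataset(ids, (0.6, 0.2, 0.2), 5)
        b = split_dataset(ids, (0.6, 0.2, 0.2), 5)
        c = split_dataset(ids, (0.6, 0.2, 0.2), 6)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        assert a.train_ids != c.train_ids
        assert (len(c.train_ids), len(c.val_ids), len(c.test_ids)) == (30, 10, 10)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            split_dataset(["a", "a", "b"], (0.5, 0.25, 0.25), 0)

    @given(n=st.integers(4, 200), seed=st.integers(0, 2**31 - 1))
    def test_partition_property(self, n, seed):
        ids = [f"id{i}" for i in range(n)]
        s = split_dataset(ids, (0.64, 0.16, 0.20), seed)
        parts = [set(s.train_ids), set(s.val_ids), set(s.test_ids)]
        assert parts[0] | parts[1] | parts[2] == set(ids)
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_manifest_round_trip(self, tmp_path):
        s = split_dataset([f"s{i}" for i in range(20)], (0.5, 0.25, 0.25), 1)
        write_split_manifest(s, tmp_path / "split.tsv")
        back = read_split_manifest(tmp_path / "split.tsv")
        assert back.train_ids == s.train_ids
        assert back.val_ids == s.val_ids
        assert back.test_ids == s.test_ids
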