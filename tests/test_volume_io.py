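"""Volume I/O and the smooth/log/scale/mask post-processing chain."""

import numpy as np
import pytest

from dbmorph.volume_io import (FWHM_TO_SIGMA, BrainMask, DegenerateScaleError,
                               HeaderReadError, InvalidJacobianError,
                               JacobianVolume, MissingVolumeError,
                               NonVolumetricImageError, apply_mask,
                               gaussian_smooth, log_transform, preprocess_chain,
                               read_volume, scale_dataset_unit_interval,
                               write_volume)


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path):
        v = JacobianVolume(np.ones((4, 4, 4)))
        write_volume(v, tmp_path / "v.nii.gz")
        back = read_volume(tmp_path / "v.nii.gz")
        np.testing.assert_array_equal(back.voxels, v.voxels)

    def test_full_resolution_dims_reported(self, tmp_path):
        v = JacobianVolume(np.zeros((121, 145, 121), dtype=np.float32))
        write_volume(v, tmp_path / "full.nii.gz")
        assert read_volume(tmp_path / "full.nii.gz").dims == (121, 145, 121)

    def test_specific_voxel_round_trip(self, tmp_path):
        data = np.zeros((5, 6, 7))
        data[2, 3, 1] = 7.5
        write_volume(JacobianVolume(data), tmp_path / "v.nii.gz")
        assert read_volume(tmp_path / "v.nii.gz").voxels[2, 3, 1] == 7.5

    def test_voxel_size_round_trip(self, tmp_path):
        v = JacobianVolume(np.zeros((4, 4, 4)), voxel_size_mm=(2.0, 2.5, 3.0))
        write_volume(v, tmp_path / "v.nii.gz")
        assert read_volume(tmp_path / "v.nii.gz").voxel_size_mm == (2.0, 2.5, 3.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(MissingVolumeError):
            read_volume(tmp_path / "absent.nii.gz")

    def test_non_3d_image(self, tmp_path):
        import nibabel as nib
        img = nib.Nifti1Image(np.zeros((3, 3, 3, 2)), np.eye(4))
        nib.save(img, str(tmp_path / "fourd.nii.gz"))
        with pytest.raises(NonVolumetricImageError):
            read_volume(tmp_path / "fourd.nii.gz")

    def test_unreadable_header(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"this is not a nifti header")
        with pytest.raises(HeaderReadError):
            read_volume(bad)


class TestGaussianSmooth:
    def test_constant_volume_unchanged(self):
        v = JacobianVolume(np.full((36, 36, 36), 3.25))
        out = gaussian_smooth(v, fwhm_mm=8.0)
        # interior voxels untouched by constant-field convolution; the zero-
        # padded border region (kernel truncated at 4 sigma ~ 14 voxels)
        # shrinks toward the boundary
        np.testing.assert_allclose(out.voxels[16:20, 16:20, 16:20], 3.25,
                                   rtol=1e-10)

    def test_sigma_closed_form(self):
        assert 8.0 / FWHM_TO_SIGMA == pytest.approx(3.3972872, abs=1e-6)

    def test_impulse_response_matches_analytic_gaussian(self):
        """Convolving a delta yields the kernel; compare to the separable
        analytic Gaussian density with sigma = fwhm / (2 sqrt(2 ln 2))."""
        n = 33
        data = np.zeros((n, n, n))
        c = n // 2
        data[c, c, c] = 1.0
        out = gaussian_smooth(JacobianVolume(data), fwhm_mm=8.0).voxels
        sigma = 8.0 / FWHM_TO_SIGMA
        ax = np.arange(n) - c
        g1 = np.exp(-ax ** 2 / (2 * sigma ** 2)) / (np.sqrt(2 * np.pi) * sigma)
        analytic = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        assert np.abs(out - analytic).max() < 1e-6

    def test_interior_impulse_conserves_sum(self):
        data = np.zeros((40, 40, 40))
        data[20, 20, 20] = 5.0
        out = gaussian_smooth(JacobianVolume(data), fwhm_mm=8.0).voxels
        assert out.sum() == pytest.approx(5.0, rel=1e-6)

    def test_rejects_bad_inputs(self):
        v = JacobianVolume(np.ones((8, 8, 8)))
        with pytest.raises(ValueError):
            gaussian_smooth(v, fwhm_mm=0.0)
        with pytest.raises(ValueError):
            gaussian_smooth(JacobianVolume(np.ones((8, 8, 8)),
                                           voxel_size_mm=(0.0, 1.0, 1.0)))


class TestLogTransform:
    @pytest.mark.parametrize("value,expected", [
        (1.0, 0.0), (np.e, 1.0), (0.5, -0.6931471805599453)])
    def test_pointwise_values(self, value, expected):
        v = JacobianVolume(np.full((3, 3, 3), value))
        assert log_transform(v).voxels[1, 1, 1] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_in_mask_rejected(self):
        data = np.ones((3, 3, 3))
        data[0, 0, 0] = 0.0
        with pytest.raises(InvalidJacobianError):
            log_transform(JacobianVolume(data))
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool))
        with pytest.raises(InvalidJacobianError):
            log_transform(JacobianVolume(data), mask)

    def test_out_of_mask_zeros_tolerated(self):
        data = np.ones((3, 3, 3))
        data[0, 0, 0] = 0.0
        m = np.ones((3, 3, 3), dtype=bool)
        m[0, 0, 0] = False
        out = log_transform(JacobianVolume(data), BrainMask(m))
        assert out.voxels[0, 0, 0] == 0.0


class TestUnitScaling:
    def test_linear_map_endpoints(self):
        v = JacobianVolume(np.array([[[-1.0, 0.0, 1.0]]]), stage="logged")
        out = scale_dataset_unit_interval([v])[0]
        np.testing.assert_allclose(out.voxels, [[[0.0, 0.5, 1.0]]])

    def test_shared_affine_across_volumes(self):
        a = JacobianVolume(np.array([[[-2.0, 0.0]]]), stage="logged")
        b = JacobianVolume(np.array([[[0.0, 2.0]]]), stage="logged")
        sa, sb = scale_dataset_unit_interval([a, b])
        assert sa.voxels[0, 0, 1] == pytest.approx(0.5)
        assert sb.voxels[0, 0, 0] == pytest.approx(0.5)

    def test_global_extrema_exact(self, rng):
        vols = [JacobianVolume(rng.normal(size=(6, 6, 6)), stage="logged")
                for _ in range(5)]
        out = scale_dataset_unit_interval(vols)
        allv = np.concatenate([v.voxels.ravel() for v in out])
        assert allv.min() == 0.0 and allv.max() == 1.0

    def test_idempotent_once_applied(self, rng):
        vols = [JacobianVolume(rng.normal(size=(5, 5, 5)), stage="logged")
                for _ in range(3)]
        once = scale_dataset_unit_interval(vols)
        twice = scale_dataset_unit_interval(once)
        for u, w in zip(once, twice):
            np.testing.assert_allclose(u.voxels, w.voxels, atol=1e-14)

    def test_degenerate_rejected(self):
        v = JacobianVolume(np.zeros((3, 3, 3)), stage="logged")
        with pytest.raises(DegenerateScaleError):
            scale_dataset_unit_interval([v])


class TestApplyMask:
    def test_all_ones_mask_is_identity(self, rng):
        v = JacobianVolume(rng.random((4, 4, 4)))
        out = apply_mask(v, BrainMask(np.ones((4, 4, 4), dtype=bool)))
        np.testing.assert_array_equal(out.voxels, v.voxels)

    def test_all_zero_mask_rejected(self):
        with pytest.raises(ValueError):
            BrainMask(np.zeros((4, 4, 4), dtype=bool))

    def test_half_grid_conservation(self, rng):
        data = rng.random((6, 6, 6))
        m = np.zeros((6, 6, 6), dtype=bool)
        m[:3] = True
        out = apply_mask(JacobianVolume(data), BrainMask(m))
        assert out.voxels.sum() == pytest.approx(data[:3].sum())
        assert np.all(out.voxels[3:] == 0)

    def test_dims_mismatch(self, rng):
        with pytest.raises(ValueError):
            apply_mask(JacobianVolume(rng.random((4, 4, 4))),
                       BrainMask(np.ones((5, 5, 5), dtype=bool)))


def test_preprocess_chain_deterministic(rng):
    """Identical raw inputs give bit-identical processed outputs."""
    vols = [JacobianVolume(np.exp(rng.normal(0, 0.1, size=(12, 12, 12))))
            for _ in range(3)]
    mask = BrainMask(np.ones((12, 12, 12), dtype=bool))
    a = preprocess_chain(vols, mask)
    b = preprocess_chain(vols, mask)
    for u, w in zip(a, b):
        assert np.array_equal(u.voxels, w.voxels)
        assert u.stage == "scaled"
        assert u.voxels.min() >= 0.0 and u.voxels.max() <= 1.0
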