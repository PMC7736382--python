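import numpy as np
import nibabel as nib
import pytest

from petlymph import (
    Modality,
    ScanMeta,
    Volume,
    body_mask,
    compute_suv,
    normalize,
    read_volume,
    resample_isotropic,
    write_volume,
)
from petlymph.image_model import F18_HALF_LIFE_MIN


class TestIO:
    def test_round_trip_preserves_data_and_grid(self, tmp_path):
        v = Volume(np.ones((10, 10, 10), np.float32), spacing=(2, 2, 2), origin=(1, -3, 5))
        path = tmp_path / "v.nii.gz"
        write_volume(v, path)
        back = read_volume(path, Modality.PET_SUV)
        np.testing.assert_array_equal(back.data, v.data)
        assert back.spacing == v.spacing
        assert back.origin == v.origin

    def test_label_round_trip_is_voxel_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        v = Volume(rng.integers(0, 5, size=(8, 8, 8)), spacing=(2, 2, 2), modality=Modality.LABEL)
        write_volume(v, tmp_path / "m.nii.gz")
        back = read_volume(tmp_path / "m.nii.gz", Modality.LABEL)
        np.testing.assert_array_equal(back.data, v.data)

    def test_float_round_trip_within_float32(self, tmp_path):
        rng = np.random.default_rng(1)
        v = Volume(rng.random((6, 6, 6)).astype(np.float32) * 20, spacing=(2, 2, 2))
        write_volume(v, tmp_path / "p.nii.gz")
        back = read_volume(tmp_path / "p.nii.gz", Modality.PET_SUV)
        np.testing.assert_allclose(back.data, v.data, rtol=1e-6)

    def test_4d_image_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4, 4, 2), np.float32), np.eye(4))
        nib.save(img, tmp_path / "v4.nii.gz")
        with pytest.raises(ValueError, match="3D"):
            read_volume(tmp_path / "v4.nii.gz", Modality.PET_SUV)

    def test_non_integer_label_file_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.full((4, 4, 4), 0.5, np.float32), np.eye(4))
        nib.save(img, tmp_path / "half.nii.gz")
        with pytest.raises(ValueError, match="LABEL"):
            read_volume(tmp_path / "half.nii.gz", Modality.LABEL)

    def test_oblique_affine_rejected(self, tmp_path):
        aff = np.eye(4)
        aff[0, 1] = 0.5
        img = nib.Nifti1Image(np.zeros((4, 4, 4), np.float32), aff)
        nib.save(img, tmp_path / "obl.nii.gz")
        with pytest.raises(ValueError, match="oblique|diagonal"):
            read_volume(tmp_path / "obl.nii.gz", Modality.CT_HU)


class TestVolumeInvariants:
    def test_probability_range_enforced(self):
        with pytest.raises(ValueError):
            Volume(np.full((3, 3, 3), 1.5), spacing=(1, 1, 1), modality=Modality.PROBABILITY)

    def test_nonfinite_rejected(self):
        data = np.zeros((3, 3, 3))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            Volume(data, spacing=(1, 1, 1))

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            Volume(np.zeros((3, 3, 3)), spacing=(1, 0, 1))


class TestSUV:
    def test_analytic_unit_case(self):
        act = Volume(np.full((4, 4, 4), 2000.0), spacing=(2, 2, 2))
        meta = ScanMeta(injected_dose_bq=1e8, body_weight_kg=50.0)
        suv = compute_suv(act, meta)
        np.testing.assert_allclose(suv.data, 1.0, rtol=1e-6)
        assert suv.modality is Modality.PET_SUV

    def test_one_half_life_doubles_suv(self):
        act = Volume(np.full((4, 4, 4), 2000.0), spacing=(2, 2, 2))
        meta = ScanMeta(1e8, 50.0, injection_to_scan_min=F18_HALF_LIFE_MIN)
        np.testing.assert_allclose(compute_suv(act, meta).data, 2.0, rtol=1e-6)

    def test_zero_activity_gives_zero(self):
        act = Volume(np.zeros((4, 4, 4)), spacing=(2, 2, 2))
        assert compute_suv(act, ScanMeta(1e8, 50.0)).data.max() == 0.0

    def test_invalid_meta_rejected(self):
        with pytest.raises(ValueError):
            ScanMeta(injected_dose_bq=0.0, body_weight_kg=50.0)
        with pytest.raises(ValueError):
            ScanMeta(injected_dose_bq=1e8, body_weight_kg=-1.0)


class TestResample:
    def test_constant_volume_stays_constant(self):
        v = Volume(np.full((10, 10, 10), 3.0), spacing=(4, 4, 4))
        out = resample_isotropic(v, 2.0)
        np.testing.assert_allclose(out.data, 3.0, atol=1e-6)

    def test_size_arithmetic_preserves_extent(self):
        v = Volume(np.zeros((10, 10, 10)), spacing=(4, 4, 4))
        out = resample_isotropic(v, 2.0)
        assert out.shape == (20, 20, 20)
        assert out.spacing == (2.0, 2.0, 2.0)
        assert out.origin == v.origin

    def test_binary_label_stays_binary_under_nearest(self):
        rng = np.random.default_rng(2)
        v = Volume(
            (rng.random((9, 9, 9)) > 0.7).astype(np.int32),
            spacing=(3, 3, 3),
            modality=Modality.LABEL,
        )
        out = resample_isotropic(v, 2.0, mode="nearest")
        assert set(np.unique(out.data)) <= {0, 1}

    def test_linear_mode_forbidden_for_labels(self):
        v = Volume(np.zeros((4, 4, 4), np.int32), spacing=(2, 2, 2), modality=Modality.LABEL)
        with pytest.raises(ValueError):
            resample_isotropic(v, 2.0, mode="linear")

    def test_identity_at_own_spacing(self):
        rng = np.random.default_rng(3)
        v = Volume(rng.random((8, 8, 8)).astype(np.float32), spacing=(2, 2, 2))
        out = resample_isotropic(v, 2.0)
        np.testing.assert_allclose(out.data, v.data, atol=1e-5)


class TestBodyMask:
    @staticmethod
    def _ellipsoid_ct(cavity=False, two_bodies=False):
        ct = np.full((24, 24, 24), -1000.0)
        x, y, z = np.ogrid[0:24, 0:24, 0:24]
        body = ((x - 12) / 8.0) ** 2 + ((y - 12) / 8.0) ** 2 + ((z - 12) / 10.0) ** 2 <= 1
        ct[body] = 0.0
        if cavity:
            ct[10:13, 10:13, 10:13] = -1000.0
        if two_bodies:
            ct[0:2, 0:2, 0:2] = 0.0
        return Volume(ct, spacing=(2, 2, 2), modality=Modality.CT_HU), body

    def test_recovers_ellipsoid(self):
        ct, body = self._ellipsoid_ct()
        np.testing.assert_array_equal(body_mask(ct).data.astype(bool), body)

    def test_internal_air_cavity_filled(self):
        ct, body = self._ellipsoid_ct(cavity=True)
        np.testing.assert_array_equal(body_mask(ct).data.astype(bool), body)

    def test_only_largest_component_kept(self):
        ct, body = self._ellipsoid_ct(two_bodies=True)
        out = body_mask(ct).data.astype(bool)
        np.testing.assert_array_equal(out, body)

    def test_all_air_ct_rejected(self):
        ct = Volume(np.full((6, 6, 6), -1000.0), spacing=(2, 2, 2), modality=Modality.CT_HU)
        with pytest.raises(ValueError):
            body_mask(ct)


class TestNormalize:
    @staticmethod
    def _mask(shape, sel):
        m = np.zeros(shape, np.int32)
        m[sel] = 1
        return Volume(m, spacing=(2, 2, 2), modality=Modality.LABEL)

    def test_mask_statistics_after_normalization(self):
        rng = np.random.default_rng(4)
        v = Volume(rng.normal(5, 3, size=(10, 10, 10)), spacing=(2, 2, 2))
        mask = self._mask(v.shape, np.s_[2:8, 2:8, 2:8])
        out = normalize(v, mask)
        inside = out.data[mask.data > 0]
        assert abs(inside.mean()) < 1e-6
        assert abs(inside.var() - 1.0) < 1e-5

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        v = Volume(rng.normal(size=(8, 8, 8)), spacing=(2, 2, 2))
        mask = self._mask(v.shape, np.s_[1:7, 1:7, 1:7])
        once = normalize(v, mask)
        twice = normalize(once, mask)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-5)

    def test_three_voxel_hand_computation(self):
        # values {1,2,3}: population sigma^2 = 2/3 -> {-sqrt(3/2), 0, +sqrt(3/2)}
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [1.0, 2.0, 3.0]
        mask = self._mask(data.shape, np.s_[:, :, :])
        out = normalize(Volume(data, spacing=(2, 2, 2)), mask)
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(out.data[:, 0, 0], expected, rtol=1e-6)

    def test_zero_variance_rejected(self):
        v = Volume(np.ones((4, 4, 4)), spacing=(2, 2, 2))
        mask = self._mask(v.shape, np.s_[0:2, 0:2, 0:2])
        with pytest.raises(ValueError):
            normalize(v, mask)
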