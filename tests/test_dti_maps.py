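"""Scalar-map formulas, NIfTI round-trips and ROI slice extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtibow.dti_maps import (
    EigenvalueVolume,
    RoiMask,
    ScalarMapVolume,
    extract_roi_slices,
    read_volume,
    rescale_to_8bit,
    scalar_maps_from_eigenvalues,
    write_volume,
)


def _maps_at(l1, l2, l3):
    ev = EigenvalueVolume(
        lam1=np.full((1, 1, 1), l1),
        lam2=np.full((1, 1, 1), l2),
        lam3=np.full((1, 1, 1), l3),
    )
    md, fa, rd = scalar_maps_from_eigenvalues(ev)
    return md.data.item(), fa.data.item(), rd.data.item()


def _fa_oracle(l1, l2, l3):
    # independent scalar evaluation of the standard definitions
    md = (l1 + l2 + l3) / 3
    num = ((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2) ** 0.5
    den = (l1**2 + l2**2 + l3**2) ** 0.5
    return (1.5**0.5) * num / den if den > 0 else 0.0


class TestScalarMapFormulas:
    def test_isotropic_tensor(self):
        md, fa, rd = _maps_at(1e-3, 1e-3, 1e-3)
        assert md == pytest.approx(1e-3, abs=1e-12)
        assert fa == pytest.approx(0.0, abs=1e-10)
        assert rd == pytest.approx(1e-3, abs=1e-12)

    def test_stick_tensor_attains_maximal_fa(self):
        md, fa, rd = _maps_at(1e-3, 0.0, 0.0)
        assert md == pytest.approx(1e-3 / 3, abs=1e-12)
        assert fa == pytest.approx(1.0, abs=1e-10)
        assert rd == 0.0

    def test_anisotropic_triple_matches_scalar_oracle(self):
        l = (1.7e-3, 0.4e-3, 0.3e-3)
        md, fa, rd = _maps_at(*l)
        assert md == pytest.approx(sum(l) / 3, abs=1e-12)
        assert rd == pytest.approx((l[1] + l[2]) / 2, abs=1e-12)
        assert fa == pytest.approx(_fa_oracle(*l), abs=1e-10)

    def test_negative_eigenvalues_clamped_with_warning(self):
        ev = EigenvalueVolume(
            lam1=np.full((1, 1, 1), 1e-3),
            lam2=np.full((1, 1, 1), 1e-4),
            lam3=np.full((1, 1, 1), -1e-5),
        )
        with pytest.warns(UserWarning, match="clamped"):
            _, _, rd = scalar_maps_from_eigenvalues(ev)
        assert rd.data.item() == pytest.approx(0.5e-4)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.tuples(
            st.floats(0, 3e-3), st.floats(0, 3e-3), st.floats(0, 3e-3)
        )
    )
    def test_map_invariants(self, lams):
        md, fa, rd = _maps_at(*lams)
        l1 = max(lams)
        assert 0.0 <= fa <= 1.0
        assert md >= rd - 1e-15
        if abs(l1 - md) < 1e-15:
            # MD = RD and FA = 0 exactly when the tensor is isotropic
            assert md == pytest.approx(rd, abs=1e-12)
            assert fa == pytest.approx(0.0, abs=1e-6)


class TestVolumeIO:
    def test_roundtrip_preserves_data_and_spacing(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = ScalarMapVolume(
            rng.random((8, 7, 6)).astype(np.float32), "MD", (1.3, 1.3, 2.7)
        )
        p = write_volume(vol, tmp_path / "md.nii.gz")
        back = read_volume(p, expected_kind="MD")
        np.testing.assert_array_equal(back.data, vol.data)
        assert back.spacing == pytest.approx(vol.spacing)
        assert back.kind == "MD"

    def test_acquisition_geometry_roundtrip(self, tmp_path):
        # full scan-matrix geometry: 256 x 256 x 59 voxels of 1.3 x 1.3 x 2.7 mm
        vol = ScalarMapVolume(
            np.zeros((256, 256, 59), dtype=np.float32), "FA", (1.3, 1.3, 2.7)
        )
        back = read_volume(write_volume(vol, tmp_path / "fa.nii.gz"), "FA")
        assert back.data.shape == (256, 256, 59)
        assert back.spacing == pytest.approx((1.3, 1.3, 2.7))

    def test_2d_input_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(np.zeros((4, 4), dtype=np.float32), np.eye(4)),
            str(tmp_path / "flat.nii"),
        )
        with pytest.raises(ValueError, match="3-D"):
            read_volume(tmp_path / "flat.nii")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii")

    def test_fa_out_of_range_clipped_with_warning(self, tmp_path):
        data = np.full((4, 4, 4), 0.5, dtype=np.float32)
        data[0, 0, 0] = 1.5
        p = write_volume(ScalarMapVolume(data, None, (1, 1, 1)), tmp_path / "fa.nii")
        with pytest.warns(UserWarning, match="clipping"):
            back = read_volume(p, expected_kind="FA")
        assert back.data.max() <= 1.0


class TestRoiSlices:
    @staticmethod
    def _cuboid_mask(shape, r, c, z):
        m = np.zeros(shape, dtype=np.uint8)
        m[r[0] : r[1], c[0] : c[1], z[0] : z[1]] = 1
        return RoiMask(m)

    def test_slice_count_and_indices(self):
        vol = ScalarMapVolume(np.random.default_rng(0).random((32, 32, 20)))
        mask = self._cuboid_mask((32, 32, 20), (5, 15), (8, 20), (10, 15))
        slices = extract_roi_slices(vol, mask, axis=2, min_roi_pixels=16)
        assert [s.slice_index for s in slices] == [10, 11, 12, 13, 14]

    def test_bboxes_match_brute_force_scan(self):
        rng = np.random.default_rng(1)
        vol = ScalarMapVolume(rng.random((32, 32, 20)))
        mask = self._cuboid_mask((32, 32, 20), (5, 15), (8, 20), (3, 9))
        for s in extract_roi_slices(vol, mask, axis=2, min_roi_pixels=16):
            m2d = mask.data[:, :, s.slice_index]
            rows = [r for r in range(32) if m2d[r].any()]
            cols = [c for c in range(32) if m2d[:, c].any()]
            assert s.bbox == (rows[0], cols[0], rows[-1] + 1, cols[-1] + 1)
            assert (s.pixels[~s.mask] == 0).all()

    def test_count_equals_brute_force_threshold_count(self):
        rng = np.random.default_rng(2)
        vol = ScalarMapVolume(rng.random((16, 16, 12)))
        mask = RoiMask((rng.random((16, 16, 12)) > 0.85).astype(np.uint8))
        thr = 20
        slices = extract_roi_slices(vol, mask, axis=2, min_roi_pixels=thr)
        expected = sum(
            1 for z in range(12) if mask.data[:, :, z].sum() >= thr
        )
        assert len(slices) == expected

    def test_empty_mask_rejected(self):
        vol = ScalarMapVolume(np.ones((8, 8, 8)))
        with pytest.raises(ValueError, match="empty"):
            extract_roi_slices(vol, RoiMask(np.zeros((8, 8, 8), dtype=np.uint8)))

    def test_shape_mismatch_rejected(self):
        vol = ScalarMapVolume(np.ones((8, 8, 8)))
        with pytest.raises(ValueError, match="grid"):
            extract_roi_slices(vol, RoiMask(np.ones((8, 8, 9), dtype=np.uint8)))


class TestRescale:
    def test_full_range_endpoints(self):
        vals = np.linspace(0.2, 0.8, 49).reshape(7, 7)
        out = rescale_to_8bit(vals, lo=0, hi=100)
        assert out.min() == 0 and out.max() == 255
        assert out[0, 0] == 0 and out[-1, -1] == 255

    def test_constant_slice_maps_to_128(self):
        out = rescale_to_8bit(np.full((5, 5), 0.42))
        assert (out == 128).all()

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.random((12, 12))
        roi = rng.random((12, 12)) > 0.3
        lo_p, hi_p = np.percentile(vals[roi], [1, 99])
        out = rescale_to_8bit(vals, roi, 1, 99)
        for i in range(12):
            for j in range(12):
                if not roi[i, j]:
                    assert out[i, j] == 0
                else:
                    x = min(max((vals[i, j] - lo_p) / (hi_p - lo_p), 0.0), 1.0)
                    assert out[i, j] == round(x * 255)
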