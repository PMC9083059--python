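"""Domain types, I/O round-trips, and analytic VOI geometry."""

import numpy as np
import pytest

from radstab import (
    FormatError,
    GeometryError,
    CongruenceError,
    EmptyMaskError,
    ImageVolume,
    VOIMask,
    extract_roi,
    make_cylinder_mask,
    make_sphere_mask,
    read_volume,
    write_volume,
)


class TestImageVolume:
    def test_invariants(self):
        with pytest.raises(FormatError):
            ImageVolume(np.zeros((4, 4)), (1, 1, 1))  # 2D
        with pytest.raises(FormatError):
            ImageVolume(np.zeros((4, 4, 4)), (1, -1, 1))
        with pytest.raises(FormatError):
            ImageVolume(np.full((2, 2, 2), np.inf), (1, 1, 1))

    def test_voxel_volume(self):
        vol = ImageVolume(np.zeros((2, 2, 2)), (1.5, 1.5, 3.0))
        assert vol.voxel_volume == pytest.approx(6.75)


class TestIO:
    @pytest.mark.parametrize("ext", [".nii", ".nii.gz", ".nrrd"])
    def test_round_trip(self, tmp_path, rng, ext):
        vol = ImageVolume(
            rng.normal(100, 5, (4, 4, 4)).astype(np.float32),
            (1.5, 1.5, 1.5),
            origin=(-3.0, 0.0, 2.0),
        )
        path = tmp_path / f"vol{ext}"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.data, vol.data, rtol=1e-6)
        assert back.spacing == pytest.approx(vol.spacing)

    def test_nrrd_and_nifti_agree(self, tmp_path, rng):
        """The same array written through both formats reads back equal."""
        vol = ImageVolume(rng.normal(0, 1, (5, 6, 7)), (1.0, 1.5, 2.0))
        write_volume(vol, tmp_path / "a.nii.gz")
        write_volume(vol, tmp_path / "a.nrrd")
        a = read_volume(tmp_path / "a.nii.gz")
        b = read_volume(tmp_path / "a.nrrd")
        np.testing.assert_allclose(a.data, b.data, rtol=1e-6)
        assert a.spacing == pytest.approx(b.spacing)

    def test_non_3d_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((4, 4)), np.eye(4)), tmp_path / "2d.nii")
        with pytest.raises(FormatError):
            read_volume(tmp_path / "2d.nii")

    def test_unknown_extension(self, tmp_path):
        with pytest.raises(FormatError):
            read_volume(tmp_path / "vol.mha")


class TestCylinderMask:
    def test_volume_within_5pct(self):
        """r=8.2 mm, h=20 mm on a 1.5 mm grid: ~4.2 cm^3 analytic volume."""
        vol = ImageVolume(np.zeros((32, 32, 32)), (1.5, 1.5, 1.5))
        c = (23.25, 23.25, 23.25)
        mask = make_cylinder_mask(vol, c, radius=8.2, height=20.0)
        measured = mask.voxel_count * vol.voxel_volume
        analytic = np.pi * 8.2**2 * 20.0
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_determinism(self):
        vol = ImageVolume(np.zeros((16, 16, 16)), (1.5, 1.5, 1.5))
        a = make_cylinder_mask(vol, (11.25, 11.25, 11.25), 5.0, 10.0)
        b = make_cylinder_mask(vol, (11.25, 11.25, 11.25), 5.0, 10.0)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_tiny_cylinder_between_voxel_centers(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), (1.0, 1.0, 1.0))
        with pytest.raises(GeometryError):
            make_cylinder_mask(vol, (3.5, 3.5, 3.5), 0.3, 0.4)

    def test_outside_grid_rejected(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), (1.0, 1.0, 1.0))
        with pytest.raises(GeometryError):
            make_cylinder_mask(vol, (3.5, 3.5, 3.5), 10.0, 4.0)


class TestSphereMask:
    def test_volume_within_5pct_anisotropic(self):
        """r=14.95 mm (~14 cm^3) on a 1.5 x 1.5 x 3.0 mm grid."""
        vol = ImageVolume(np.zeros((32, 32, 16)), (1.5, 1.5, 3.0))
        c = (23.25, 23.25, 22.5)
        mask = make_sphere_mask(vol, c, radius=14.95)
        measured = mask.voxel_count * vol.voxel_volume
        analytic = 4.0 / 3.0 * np.pi * 14.95**3
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_zero_radius_rejected(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), (1.0, 1.0, 1.0))
        with pytest.raises(GeometryError):
            make_sphere_mask(vol, (3.5, 3.5, 3.5), 0.0)

    def test_grid_symmetries(self):
        """Ball on a voxel center is invariant under the 48 cube symmetries."""
        vol = ImageVolume(np.zeros((15, 15, 15)), (1.0, 1.0, 1.0))
        mask = make_sphere_mask(vol, (7.0, 7.0, 7.0), 5.2).mask
        import itertools

        for perm in itertools.permutations(range(3)):
            for flips in itertools.product([False, True], repeat=3):
                m = np.transpose(mask, perm)
                for axis, f in enumerate(flips):
                    if f:
                        m = np.flip(m, axis=axis)
                np.testing.assert_array_equal(m, mask)

    def test_volume_error_decreases_with_refinement(self):
        analytic = 4.0 / 3.0 * np.pi * 10.0**3
        errors = []
        for spacing, n in ((2.0, 16), (1.0, 32)):
            vol = ImageVolume(np.zeros((n, n, n)), (spacing,) * 3)
            c = ((n - 1) / 2.0 * spacing,) * 3
            mask = make_sphere_mask(vol, c, 10.0)
            errors.append(abs(mask.voxel_count * vol.voxel_volume - analytic))
        assert errors[1] < errors[0]


class TestExtractRoi:
    def test_full_mask_identity(self, rng):
        data = rng.normal(0, 1, (2, 2, 2))
        vol = ImageVolume(data, (1.0, 1.0, 1.0))
        mask = VOIMask(np.ones((2, 2, 2), bool), spacing=vol.spacing)
        roi = extract_roi(vol, mask)
        assert roi.voxel_count == 8
        np.testing.assert_allclose(np.sort(roi.values), np.sort(data.ravel()))

    def test_single_voxel(self):
        vol = ImageVolume(np.arange(27.0).reshape(3, 3, 3), (1.0, 1.0, 1.0))
        m = np.zeros((3, 3, 3), bool)
        m[1, 2, 0] = True
        roi = extract_roi(vol, VOIMask(m, spacing=vol.spacing))
        assert roi.values.tolist() == [vol.data[1, 2, 0]]

    def test_checkerboard_scan_order(self):
        """x-fastest ordering against hand enumeration on a 2x2x2 board."""
        data = np.arange(8.0).reshape(2, 2, 2)  # data[x, y, z]
        vol = ImageVolume(data, (1.0, 1.0, 1.0))
        m = np.indices((2, 2, 2)).sum(axis=0) % 2 == 0
        roi = extract_roi(vol, VOIMask(m, spacing=vol.spacing))
        # Foreground (x+y+z even): scan order x fastest, then y, then z:
        # (0,0,0), (1,1,0), (1,0,1), (0,1,1)
        expected = [data[0, 0, 0], data[1, 1, 0], data[1, 0, 1], data[0, 1, 1]]
        assert roi.values.tolist() == expected

    def test_empty_and_mismatched(self):
        vol = ImageVolume(np.zeros((2, 2, 2)), (1.0, 1.0, 1.0))
        with pytest.raises(EmptyMaskError):
            extract_roi(vol, VOIMask(np.zeros((2, 2, 2), bool), spacing=vol.spacing))
        with pytest.raises(CongruenceError):
            extract_roi(vol, VOIMask(np.ones((3, 3, 3), bool), spacing=vol.spacing))
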