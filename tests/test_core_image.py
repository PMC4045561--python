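"""Volume I/O, reslicing, AC-PC reorientation and exact sagittal flipping."""

import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symatlas.core_image import (
    ImageVolume,
    Landmarks,
    acpc_transform,
    flip_sagittal,
    is_flip_exact,
    make_symmetric_grid,
    read_volume,
    reorient_acpc,
    reslice_isotropic,
    write_volume,
)
from symatlas.errors import FormatError, GridError


def _random_volume(rng, shape=(8, 8, 8)):
    shape, affine = make_symmetric_grid((3.0, 7.0, 7.0), 1.0)
    data = rng.random(shape).astype(np.float32)
    return ImageVolume(data, affine)


class TestIO:
    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = _random_volume(rng)
        p = tmp_path / "v.nii.gz"
        write_volume(vol, p)
        back = read_volume(p)
        np.testing.assert_array_equal(back.data, vol.data)
        np.testing.assert_allclose(back.affine, vol.affine, atol=1e-5)
        np.testing.assert_allclose(back.voxel_size, vol.voxel_size, atol=1e-5)

    def test_probability_values_survive_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        vol = _random_volume(rng)  # values already in [0, 1]
        p = tmp_path / "p.nii.gz"
        write_volume(vol, p)
        back = read_volume(p)
        assert back.data.min() >= 0.0 and back.data.max() <= 1.0
        np.testing.assert_array_equal(back.data, vol.data)

    def test_non_ras_file_is_reoriented(self, tmp_path):
        """An LPS-stored file reads back with identical world-space content."""
        rng = np.random.default_rng(2)
        vol = _random_volume(rng)
        # store flipped along x and y with a matching LPS affine
        lps_data = vol.data[::-1, ::-1, :]
        lps_affine = vol.affine.copy()
        lps_affine[0, 0] *= -1
        lps_affine[1, 1] *= -1
        xs = vol.affine[0, 3] + np.arange(vol.shape[0]) * vol.affine[0, 0]
        ys = vol.affine[1, 3] + np.arange(vol.shape[1]) * vol.affine[1, 1]
        lps_affine[0, 3] = xs[-1]
        lps_affine[1, 3] = ys[-1]
        nib.save(nib.Nifti1Image(lps_data, lps_affine), tmp_path / "lps.nii.gz")
        back = read_volume(tmp_path / "lps.nii.gz")
        # world coordinate of three probe voxels must carry the same value
        for idx in [(0, 0, 0), (3, 2, 5), (6, 7, 1)]:
            w = vol.affine @ np.array([*idx, 1.0])
            jdx = np.linalg.solve(back.affine, w)[:3]
            jdx = tuple(np.round(jdx).astype(int))
            assert back.data[jdx] == vol.data[idx]

    def test_truncated_file_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.nii"
        p.write_bytes(b"\x00" * 100)
        with pytest.raises(FormatError):
            read_volume(p)


class TestReslice:
    def test_aligned_input_is_unchanged(self):
        shape, affine = make_symmetric_grid((4.0, 8.0, 8.0), 0.5)
        rng = np.random.default_rng(3)
        vol = ImageVolume(rng.random(shape).astype(np.float32), affine)
        out = reslice_isotropic(vol, 0.5)
        assert out.shape == vol.shape
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)

    def test_constant_volume_stays_constant(self):
        shape, affine = make_symmetric_grid((5.0, 10.0, 10.0), 1.0)
        vol = ImageVolume(np.full(shape, 7.25, dtype=np.float32), affine)
        out = reslice_isotropic(vol, 0.5)
        assert np.allclose(out.voxel_size, 0.5)
        inner = out.data[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(inner, 7.25, atol=1e-6)

    def test_mask_volume_preserved_on_anisotropic_input(self):
        """0.47x0.47x0.7 mm scanner grid -> 0.5 mm: brain volume within 2%."""
        from symatlas.phantom import PhantomSpec, generate_head_phantom

        spec = PhantomSpec(grid_mm=2.0)
        img, masks, _ = generate_head_phantom(spec)
        # resample the mask onto an anisotropic grid mimicking acquisition
        aff = np.diag([1.88, 1.88, 2.8, 1.0])
        aff[:3, 3] = masks.brain.affine[:3, 3]
        nshape = tuple(
            int(s * v / a) for s, v, a in zip(masks.brain.shape, (2, 2, 2), (1.88, 1.88, 2.8))
        )
        from symatlas.core_image import sample_at_world, _grid_world_points

        pts = _grid_world_points(nshape, aff)
        aniso = ImageVolume(
            sample_at_world(masks.brain, pts).astype(np.float32), aff
        )
        vol_before = aniso.data.sum() * np.prod(aniso.voxel_size)
        out = reslice_isotropic(aniso, 2.0)
        vol_after = out.data.sum() * np.prod(out.voxel_size)
        assert abs(vol_after - vol_before) / vol_before < 0.02

    def test_bad_target_raises(self):
        shape, affine = make_symmetric_grid((3.0, 5.0, 5.0), 1.0)
        vol = ImageVolume(np.zeros(shape, dtype=np.float32), affine)
        with pytest.raises(ValueError):
            reslice_isotropic(vol, 0.0)


class TestReorient:
    def test_canonical_landmarks_give_identity(self):
        lm = Landmarks([0, 0, 0], [0, -25, 0], [0, -10, 35])
        T = acpc_transform(lm)
        np.testing.assert_allclose(T, np.eye(4), atol=1e-12)

    def test_known_rigid_motion_is_recovered(self):
        """Rotate 10 deg about z and translate (5, 2, -3): transformed
        landmarks map back to the canonical frame within 0.25 mm."""
        th = np.deg2rad(10.0)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        t = np.array([5.0, 2.0, -3.0])
        ac, pc, ih = (
            np.array([0.0, 0, 0]),
            np.array([0.0, -25, 0]),
            np.array([0.0, -10, 35]),
        )
        lm = Landmarks(R @ ac + t, R @ pc + t, R @ ih + t)
        T = acpc_transform(lm)
        Tinv = np.linalg.inv(T)

        def to_aligned(p):
            return Tinv[:3, :3] @ p + Tinv[:3, 3]

        assert np.linalg.norm(to_aligned(lm.AC)) < 0.25
        pc_aligned = to_aligned(lm.PC)
        assert abs(pc_aligned[0]) < 0.25 and abs(pc_aligned[2]) < 0.25
        assert abs(to_aligned(lm.IH)[0]) < 0.25

    def test_rigid_transform_preserves_landmark_distances(self):
        rng = np.random.default_rng(7)
        lm = Landmarks(rng.normal(size=3), rng.normal(size=3) + 5, rng.normal(size=3) - 5)
        T = acpc_transform(lm)
        Tinv = np.linalg.inv(T)
        pts = np.stack([lm.AC, lm.PC, lm.IH])
        moved = (Tinv[:3, :3] @ pts.T + Tinv[:3, 3:4]).T
        for i in range(3):
            for j in range(i + 1, 3):
                d0 = np.linalg.norm(pts[i] - pts[j])
                d1 = np.linalg.norm(moved[i] - moved[j])
                assert abs(d0 - d1) < 1e-9

    def test_aligned_phantom_reorients_to_itself(self, phantom_2mm):
        img, _, lm = phantom_2mm
        out = reorient_acpc(img, lm)
        # same canonical frame: content at probe world points is unchanged
        from symatlas.core_image import sample_at_world

        rng = np.random.default_rng(0)
        pts = rng.uniform(-20, 20, size=(3, 50))
        np.testing.assert_allclose(
            sample_at_world(out, pts), sample_at_world(img, pts), atol=1e-3
        )

    def test_rotated_phantom_content_is_restored(self, phantom_2mm):
        img, _, lm0 = phantom_2mm
        th = np.deg2rad(10.0)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        t = np.array([5.0, 2.0, -3.0])
        M = np.eye(4)
        # moved(x) = img(R^-1 (x - t)): resample the phantom under the motion
        M[:3, :3] = R.T
        M[:3, 3] = -R.T @ t
        from symatlas.registration import apply_affine

        big_shape, big_aff = make_symmetric_grid((60.0, 140.0, 130.0), 2.0, (-8.0, 12.0))
        like = ImageVolume(np.zeros(big_shape, dtype=np.float32), big_aff)
        Minv = np.linalg.inv(M)
        moved = apply_affine(Minv, img, like=like)
        lm = Landmarks(R @ lm0.AC + t, R @ lm0.PC + t, R @ lm0.IH + t)
        out = reorient_acpc(moved, lm)
        from symatlas.core_image import sample_at_world

        rng = np.random.default_rng(1)
        pts = rng.uniform(-25, 25, size=(3, 200))
        est = sample_at_world(out, pts)
        ref = sample_at_world(img, pts)
        # interpolation softens edges; demand close agreement on most probes
        assert np.median(np.abs(est - ref)) < 1.0

    def test_collinear_landmarks_raise(self):
        with pytest.raises(ValueError):
            Landmarks([0, 0, 0], [0, -25, 0], [0, -10, 0])


class TestFlip:
    def test_flip_requires_symmetric_grid(self):
        affine = np.diag([1.0, 1, 1, 1])
        affine[:3, 3] = (0.3, 0, 0)  # x centers not symmetric about 0
        vol = ImageVolume(np.zeros((4, 4, 4), dtype=np.float32), affine)
        with pytest.raises(GridError):
            flip_sagittal(vol)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_flip_is_involution_and_preserves_multiset(self, seed):
        rng = np.random.default_rng(seed)
        shape, affine = make_symmetric_grid((3.0, 4.0, 4.0), 1.0)
        vol = ImageVolume(rng.random(shape).astype(np.float32), affine)
        f = flip_sagittal(vol)
        ff = flip_sagittal(f)
        np.testing.assert_array_equal(ff.data, vol.data)
        np.testing.assert_array_equal(np.sort(f.data.ravel()), np.sort(vol.data.ravel()))

    def test_symmetric_phantom_is_flip_invariant(self, phantom_2mm):
        img, _, _ = phantom_2mm
        assert is_flip_exact(img)
        np.testing.assert_array_equal(flip_sagittal(img).data, img.data)

    def test_left_scaled_phantom_flip_swaps_hemisphere_counts(self, phantom_2mm_asym):
        img, masks, _ = phantom_2mm_asym
        b = masks.brain
        xs = b.affine[0, 3] + np.arange(b.shape[0]) * b.affine[0, 0]
        left = int(b.data[xs < 0].sum())
        right = int(b.data[xs > 0].sum())
        fb = flip_sagittal(b)
        fleft = int(fb.data[xs < 0].sum())
        fright = int(fb.data[xs > 0].sum())
        assert left == fright and right == fleft
        assert left > right
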