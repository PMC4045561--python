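"""Affine and cosine-basis registration, inversion and averaging."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from symatlas.core_image import ImageVolume, make_symmetric_grid, flip_sagittal
from symatlas.errors import InversionError
from symatlas.phantom import PhantomSpec, generate_head_phantom
from symatlas.preprocess import make_ic_mask
from symatlas.registration import (
    AffineParams,
    DCTDeformation,
    affine_register,
    apply_affine,
    apply_deformation,
    average_deformation,
    invert_deformation,
    mirror_conjugate,
    nonlinear_register,
)


@pytest.fixture(scope="module")
def head():
    img, masks, _ = generate_head_phantom(PhantomSpec(grid_mm=2.0))
    _, weight = make_ic_mask(masks, smooth_mm=1.0)
    return img, masks, weight


def axis_coords(vol):
    return [vol.affine[a, 3] + np.arange(vol.shape[a]) * vol.affine[a, a] for a in range(3)]


def random_field(vol, k, max_mm, seed):
    rng = np.random.default_rng(seed)
    d = DCTDeformation.zeros(vol, k=k)
    d.coeffs = rng.uniform(-1.0, 1.0, d.coeffs.shape)
    u = d.displacement_on_axes(axis_coords(vol))
    d.coeffs *= max_mm / np.abs(u).max()
    return d


class TestAffine:
    def test_identity_on_self(self, head):
        img, _, w = head
        res = affine_register(img, img, w)
        p = res.transform
        assert np.all(np.abs(p.translation) < 0.1)
        assert np.all(np.abs(p.rotation) < 0.002)
        assert np.all(np.abs(p.scale - 1.0) < 0.005)

    def test_translation_recovery(self, head):
        img, _, w = head
        t = AffineParams(translation=[4.0, -3.0, 2.0])
        moving = apply_affine(t, img)  # moving(x) = img(x + t)
        res = affine_register(moving, img, w)
        # the recovered map composes with the injected one to identity
        assert np.all(np.abs(res.transform.translation + [4.0, -3.0, 2.0]) < 0.25)

    def test_isotropic_scale_recovery(self, head):
        img, _, w = head
        t = AffineParams(scale=[1.1, 1.1, 1.1])
        moving = apply_affine(t, img)
        res = affine_register(moving, img, w)
        assert np.all(np.abs(res.transform.scale - 1.0 / 1.1) < 0.01 / 1.1)

    def test_objective_trace_nonincreasing(self, head):
        img, _, w = head
        t = AffineParams(translation=[3.0, 1.0, -2.0], scale=[1.05, 0.97, 1.02])
        moving = apply_affine(t, img)
        res = affine_register(moving, img, w)
        for level in res.trace_by_level:
            assert all(b <= a + 1e-12 for a, b in zip(level, level[1:]))

    def test_gain_invariance(self, head):
        """A global intensity rescaling of the moving image is absorbed."""
        img, _, w = head
        t = AffineParams(translation=[2.0, -1.0, 1.0])
        moving = apply_affine(t, img)
        bright = moving.with_data(moving.data * 3.7)
        res = affine_register(bright, img, w)
        assert np.all(np.abs(res.transform.translation + [2.0, -1.0, 1.0]) < 0.25)

    def test_empty_weight_raises(self, head):
        img, _, w = head
        zero = w.with_data(np.zeros_like(w.data))
        with pytest.raises(ValueError):
            affine_register(img, img, zero)

    def test_mirror_equivariance(self):
        """Registering the mirrored pair yields the mirror-conjugate
        transform, within optimizer tolerance (3 seeds)."""
        F = np.diag([-1.0, 1.0, 1.0, 1.0])
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            img, masks, _ = generate_head_phantom(
                PhantomSpec(grid_mm=2.0, left_scale=1.04, seed=seed)
            )
            _, w = make_ic_mask(masks, smooth_mm=1.0)
            t = AffineParams(
                translation=rng.uniform(-3, 3, 3),
                rotation=rng.uniform(-0.05, 0.05, 3),
                scale=1 + rng.uniform(-0.03, 0.03, 3),
            )
            moving = apply_affine(t, img)
            A = affine_register(moving, img, w).transform.matrix()
            Af = affine_register(
                flip_sagittal(moving), flip_sagittal(img), flip_sagittal(w)
            ).transform.matrix()
            np.testing.assert_allclose(Af, F @ A @ F, atol=0.02)


class TestApplyAffine:
    def test_identity_is_exact(self, head):
        img, _, _ = head
        out = apply_affine(AffineParams.identity(), img)
        np.testing.assert_allclose(out.data, img.data, atol=1e-6)

    def test_full_voxel_translation_is_grid_shift(self, head):
        img, _, _ = head
        out = apply_affine(AffineParams(translation=[2.0, 0, 0]), img)  # one voxel
        np.testing.assert_array_equal(out.data[:-1], img.data[1:])

    def test_scale_changes_mask_volume_by_jacobian(self, head):
        _, masks, _ = head
        out = apply_affine(
            AffineParams(scale=[1 / 1.1] * 3), masks.brain, kind="mask", binarize=True
        )
        v0 = masks.brain.data.sum()
        v1 = out.data.sum()
        assert abs(v1 / v0 - 1.331) < 0.04

    def test_singular_transform_raises(self, head):
        img, _, _ = head
        M = np.diag([0.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            apply_affine(M, img)


class TestNonlinear:
    def test_identity_gives_near_zero_field(self, head):
        img, _, w = head
        res = nonlinear_register(img, img, w, k=6)
        u = res.transform.displacement_on_axes(axis_coords(img))
        assert np.abs(u).max() < 0.2

    def test_known_field_recovery_and_ssd_reduction(self, head):
        """An injected 3 mm order-2 cosine warp is recovered: >= 80% SSD
        reduction (measured with a single independent resampling) and
        < 1 mm mean field error inside the brain."""
        img, masks, w = head
        d_true = random_field(img, k=3, max_mm=3.0, seed=0)
        warped = apply_deformation(d_true, img)
        res = nonlinear_register(warped, img, w, k=3)
        pts = np.stack(np.meshgrid(*axis_coords(img), indexing="ij")).reshape(3, -1)
        inv = np.linalg.inv(img.affine)

        def sample(p):
            vox = inv[:3, :3] @ p + inv[:3, 3:4]
            return map_coordinates(img.data.astype(float), vox, order=1, cval=0.0)

        wf = w.data.reshape(-1)
        ref = img.data.reshape(-1)
        before = float(
            (wf * (sample(pts + d_true.displacement_at_points(pts)) - ref) ** 2).sum()
        )
        y = pts + res.transform.displacement_at_points(pts)
        after = float(
            (wf * (sample(y + d_true.displacement_at_points(y)) - ref) ** 2).sum()
        )
        assert after < 0.2 * before
        # the fitted field matches the numeric inverse of the injected one
        inv_true = invert_deformation(d_true)
        ue = res.transform.displacement_on_axes(axis_coords(img))
        ut = inv_true.displacement_on_axes(axis_coords(img))
        err = np.sqrt(((ue - ut) ** 2).sum(axis=0))
        assert err[masks.brain.data > 0.5].mean() < 1.0

    def test_objective_trace_nonincreasing(self, head):
        img, _, w = head
        d_true = random_field(img, k=3, max_mm=2.0, seed=1)
        warped = apply_deformation(d_true, img)
        res = nonlinear_register(warped, img, w, k=3)
        for level in res.trace_by_level:
            assert all(b <= a + 1e-12 for a, b in zip(level, level[1:]))

    def test_small_k_rejected(self, head):
        img, _, w = head
        with pytest.raises(ValueError):
            nonlinear_register(img, img, w, k=1)


class TestInversion:
    def test_zero_field_inverts_to_zero(self, head):
        img, _, _ = head
        d = DCTDeformation.zeros(img, k=4)
        out = invert_deformation(d)
        assert np.abs(out.coeffs).max() == 0.0

    def test_constant_displacement_inverts_to_negation(self, head):
        img, _, _ = head
        d = DCTDeformation.zeros(img, k=4)
        d.coeffs[:, 0, 0, 0] = [1.5, -2.0, 0.7]
        out = invert_deformation(d)
        u = out.displacement_at_points(np.zeros((3, 1)))
        np.testing.assert_allclose(u.ravel(), [-1.5, 2.0, -0.7], atol=1e-3)

    def test_roundtrip_residual_below_tenth_voxel(self, head):
        """compose(D, invert(D)) stays within 0.1 voxel of identity,
        checked against a dense fixed-point oracle."""
        img, _, _ = head
        vox = float(img.voxel_size[0])
        for seed in (2, 3):
            d = random_field(img, k=3, max_mm=2.0, seed=seed)
            dinv = invert_deformation(d)
            pts = np.stack(np.meshgrid(*axis_coords(img), indexing="ij")).reshape(3, -1)
            pts = pts[:, ::5]
            v = dinv.displacement_at_points(pts)
            resid = v + d.displacement_at_points(pts + v)
            assert np.sqrt((resid**2).sum(axis=0)).mean() < 0.1 * vox

    def test_folding_field_raises(self, head):
        img, _, _ = head
        d = random_field(img, k=3, max_mm=40.0, seed=4)
        with pytest.raises(InversionError):
            invert_deformation(d)


class TestAveraging:
    def test_mean_of_identical_fields_is_identity(self, head):
        img, _, _ = head
        d = random_field(img, k=4, max_mm=2.0, seed=5)
        out = average_deformation([d, d, d])
        np.testing.assert_array_equal(out.coeffs, d.coeffs)

    def test_opposite_fields_cancel(self, head):
        img, _, _ = head
        d = random_field(img, k=4, max_mm=2.0, seed=6)
        neg = DCTDeformation(
            -d.coeffs, d.domain_lo, d.domain_len, d.grid_shape, d.grid_affine
        )
        out = average_deformation([d, neg])
        assert np.abs(out.coeffs).max() == 0.0

    def test_permutation_invariance_and_linearity(self, head):
        img, _, _ = head
        ds = [random_field(img, k=3, max_mm=2.0, seed=s) for s in (7, 8, 9)]
        a = average_deformation(ds)
        b = average_deformation(ds[::-1])
        np.testing.assert_allclose(a.coeffs, b.coeffs, atol=1e-15)
        doubled = [
            DCTDeformation(2 * d.coeffs, d.domain_lo, d.domain_len, d.grid_shape, d.grid_affine)
            for d in ds
        ]
        np.testing.assert_allclose(
            average_deformation(doubled).coeffs, 2 * a.coeffs, atol=1e-12
        )

    def test_mirror_pair_average_vanishes_on_midplane(self, head):
        """Averaging a field with its sagittal mirror-conjugate leaves no
        x displacement anywhere on the x = 0 plane — exactly."""
        img, _, _ = head
        d = random_field(img, k=4, max_mm=2.0, seed=10)
        avg = average_deformation([d, mirror_conjugate(d)])
        xs, ys, zs = axis_coords(img)
        mid = np.argmin(np.abs(xs))
        assert abs(xs[mid]) < 1e-9
        u = avg.displacement_on_axes([xs[mid : mid + 1], ys, zs])
        assert np.abs(u[0]).max() == 0.0

    def test_mismatched_grids_raise(self, head):
        img, _, _ = head
        d1 = random_field(img, k=3, max_mm=1.0, seed=11)
        d2 = random_field(img, k=4, max_mm=1.0, seed=11)
        with pytest.raises(ValueError):
            average_deformation([d1, d2])


class TestApplyDeformation:
    def test_zero_field_is_identity(self, head):
        img, _, _ = head
        d = DCTDeformation.zeros(img, k=4)
        out = apply_deformation(d, img)
        np.testing.assert_allclose(out.data, img.data, atol=1e-6)

    def test_constant_field_matches_affine_translation(self, head):
        img, _, _ = head
        d = DCTDeformation.zeros(img, k=4)
        d.coeffs[:, 0, 0, 0] = [1.3, -0.8, 2.1]
        a = apply_deformation(d, img)
        b = apply_affine(AffineParams(translation=[1.3, -0.8, 2.1]), img)
        np.testing.assert_allclose(a.data, b.data, atol=1e-3)

    def test_small_field_preserves_blob_mass(self, head):
        img, _, _ = head
        xs, ys, zs = axis_coords(img)
        X, Y, Z = np.meshgrid(xs, ys - 10, zs - 10, indexing="ij")
        blob = np.exp(-(X**2 + Y**2 + Z**2) / (2 * 15.0**2)).astype(np.float32)
        vol = img.with_data(blob)
        d = random_field(img, k=3, max_mm=2.0, seed=12)
        out = apply_deformation(d, vol)
        assert abs(out.data.sum() - blob.sum()) / blob.sum() < 0.02
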