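"""Rigid MI alignment, local CC metric, SyN, field algebra, CCFM."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from neuropet.core_io import VolumeGeometry
from neuropet.phantom import insert_lesion, make_deformation
from neuropet.registration import (
    DeformationField,
    RigidTransform,
    TransformChain,
    apply_cost_mask,
    compose_chain,
    compose_fields,
    intensity_gradient,
    invert_field,
    jacobian_determinant,
    local_cc,
    mutual_information,
    rigid_register,
    syn_register,
    warp_image,
)


@pytest.fixture(scope="module")
def textured_image():
    rng = np.random.default_rng(0)
    img = gaussian_filter(rng.normal(size=(96, 96)), 4)
    img[20:70, 25:60] += 2.0
    return img


class TestMutualInformation:
    def test_self_information_equals_entropy(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(64, 64))
        mi = mutual_information(img, img)
        hist, _ = np.histogram(img, bins=32)
        p = hist / hist.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mi == pytest.approx(entropy, rel=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(64, 64))
        b = rng.normal(size=(64, 64))
        assert mutual_information(a, b, bins=16) <= 0.1

    def test_constant_image_zero(self):
        rng = np.random.default_rng(2)
        assert mutual_information(np.ones((16, 16)), rng.normal(size=(16, 16))) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mutual_information(np.ones((4, 4)), np.ones((5, 5)))


class TestRigid:
    def test_identity_registration(self, textured_image):
        tr = rigid_register(textured_image, textured_image)
        assert np.hypot(*tr.translation) <= 0.1
        assert abs(tr.angles_deg[0]) <= 0.1

    def test_known_shift_and_rotation_recovered(self, textured_image):
        true = RigidTransform((5.0,), (3.0, -2.0))
        moving = warp_image(textured_image, true.inverse())
        est = rigid_register(moving, textured_image)
        assert abs(est.angles_deg[0] - 5.0) <= 0.5
        assert abs(est.translation[0] - 3.0) <= 0.5
        assert abs(est.translation[1] + 2.0) <= 0.5

    def test_inverse_is_exact(self):
        tr = RigidTransform((12.0,), (4.0, -1.5))
        pts = np.random.default_rng(3).uniform(0, 30, (10, 2))
        back = tr.inverse().apply_points(tr.apply_points(pts, (32, 32)), (32, 32))
        np.testing.assert_allclose(back, pts, atol=1e-10)


class TestLocalCC:
    def test_identical_images_have_unit_correlation(self):
        rng = np.random.default_rng(0)
        img = gaussian_filter(rng.normal(size=(24, 24)), 1)
        score, _ = local_cc(img, img, radius=3)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(1)
        img = gaussian_filter(rng.normal(size=(24, 24)), 1)
        score, _ = local_cc(img, 2.5 * img + 3.0, radius=3)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        S = rng.normal(size=(16, 16))
        T = rng.normal(size=(16, 16))
        dS = intensity_gradient(S, T, radius=3)
        h = 1e-6
        for (i, j) in [(5, 5), (8, 3), (12, 12), (3, 10), (7, 7)]:
            Sp, Sm = S.copy(), S.copy()
            Sp[i, j] += h
            Sm[i, j] -= h
            fd = (local_cc(Sp, T, radius=3)[0] - local_cc(Sm, T, radius=3)[0]) / (2 * h)
            assert abs(fd - dS[i, j]) / max(abs(fd), 1e-12) <= 1e-3

    def test_window_larger_than_image_raises(self):
        with pytest.raises(ValueError):
            local_cc(np.ones((6, 6)), np.ones((6, 6)), radius=4)


class TestWarp:
    def test_identity_transform_preserves_image(self, textured_image):
        out = warp_image(textured_image, np.zeros((2, 96, 96)))
        np.testing.assert_allclose(out, textured_image, atol=1e-12)

    def test_nearest_warp_never_invents_labels(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 5, (32, 32)).astype(np.int32)
        field, _ = make_deformation(VolumeGeometry((32, 32), (1.0, 1.0)), 2.0,
                                    smoothness_voxels=4.0, seed=5)
        out = warp_image(labels, field, interp="nearest")
        assert set(np.unique(out)) <= set(np.unique(labels))

    def test_integer_shift_exact_under_linear_interp(self, textured_image):
        disp = np.zeros((2, 96, 96))
        disp[0] = 1.0
        out = warp_image(textured_image, disp)
        np.testing.assert_allclose(out[:-1], textured_image[1:], atol=1e-12)

    def test_invalid_interp_rejected(self, textured_image):
        with pytest.raises(ValueError):
            warp_image(textured_image, np.zeros((2, 96, 96)), interp="cubic")


class TestInvertField:
    def test_zero_field(self):
        geom = VolumeGeometry((16, 16), (1.0, 1.0))
        f = DeformationField(np.zeros((2, 16, 16)), geom)
        np.testing.assert_allclose(invert_field(f).disp, 0.0)

    def test_constant_translation(self):
        geom = VolumeGeometry((24, 24), (1.0, 1.0))
        disp = np.zeros((2, 24, 24))
        disp[0] = 1.5
        disp[1] = -0.75
        g = invert_field(DeformationField(disp, geom)).disp
        # interior voxels: inverse is the negated translation
        np.testing.assert_allclose(g[0, 4:-4, 4:-4], -1.5, atol=1e-6)
        np.testing.assert_allclose(g[1, 4:-4, 4:-4], 0.75, atol=1e-6)

    def test_random_smooth_field_self_consistency(self):
        geom = VolumeGeometry((48, 48), (1.0, 1.0))
        field, _ = make_deformation(geom, 3.0, smoothness_voxels=6.0, seed=7)
        g = invert_field(field)
        comp = compose_fields(field.disp, g.disp)
        assert np.mean(np.linalg.norm(comp, axis=0)) <= 0.05


class TestComposeChain:
    def test_field_and_its_inverse_compose_to_identity(self):
        geom = VolumeGeometry((48, 48), (1.0, 1.0))
        field, _ = make_deformation(geom, 3.0, smoothness_voxels=6.0, seed=8)
        chain = TransformChain().add(field).add(field, inverted=True)
        total = compose_chain(chain, geom)
        assert np.mean(np.linalg.norm(total.disp, axis=0)) <= 0.05

    def test_single_rigid_equals_analytic_map(self):
        geom = VolumeGeometry((32, 32), (1.0, 1.0))
        tr = RigidTransform((10.0,), (2.0, -1.0))
        total = compose_chain(TransformChain().add(tr), geom)
        np.testing.assert_allclose(total.disp, tr.to_field(geom).disp, atol=1e-6)

    def test_composed_warp_beats_sequential_interpolation(self, textured_image):
        geom = VolumeGeometry((96, 96), (1.0, 1.0))
        f1, _ = make_deformation(geom, 2.0, smoothness_voxels=8.0, seed=9)
        f2, _ = make_deformation(geom, 2.0, smoothness_voxels=8.0, seed=10)
        chain = TransformChain().add(f1).add(f2)
        composed = warp_image(textured_image, compose_chain(chain, geom))
        sequential = warp_image(warp_image(textured_image, f2), f1)
        # oracle: single warp through the exactly composed point map
        grid = np.stack(np.meshgrid(np.arange(96.), np.arange(96.), indexing="ij"))
        p1 = grid + f2.disp
        coords = p1 + np.stack([map_coordinates(c, p1, order=1, mode="nearest")
                                for c in f1.disp])
        oracle = map_coordinates(textured_image, coords, order=1, mode="constant")
        err_composed = np.mean(np.abs(composed - oracle))
        err_sequential = np.mean(np.abs(sequential - oracle))
        assert err_composed <= err_sequential

    def test_chain_point_order_matches_sequential_application(self):
        """First chain element moves the output-grid point; labels shift exactly."""
        geom = VolumeGeometry((16, 16), (1.0, 1.0))
        shift = np.zeros((2, 16, 16))
        shift[0] = 2.0  # point x -> x + 2
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[8, 8] = 7
        chain = TransformChain().add(DeformationField(shift, geom))
        out = warp_image(labels, compose_chain(chain, geom), interp="nearest")
        assert out[6, 8] == 7


class TestJacobian:
    def test_zero_field_gives_unit_determinant(self):
        geom = VolumeGeometry((16, 16), (1.0, 1.0))
        det = jacobian_determinant(DeformationField(np.zeros((2, 16, 16)), geom))
        np.testing.assert_allclose(det, 1.0)

    def test_uniform_scaling_gives_s_squared(self):
        s = 1.1
        n = 16
        geom = VolumeGeometry((n, n), (1.0, 1.0))
        grid = np.stack(np.meshgrid(np.arange(n, dtype=float),
                                    np.arange(n, dtype=float), indexing="ij"))
        disp = (s - 1.0) * grid
        det = jacobian_determinant(DeformationField(disp, geom))
        np.testing.assert_allclose(det[1:-1, 1:-1], s**2, rtol=1e-9)


class TestSyN:
    def test_identical_images_give_near_zero_field(self, phantom_128):
        _, _, structural = phantom_128
        pair = syn_register(structural, structural, levels=(4, 2), max_iter=20)
        assert np.mean(np.linalg.norm(pair.forward.disp, axis=0)) <= 0.1

    def test_metric_trace_non_decreasing_within_level(self, phantom_128):
        _, _, structural = phantom_128
        field, _ = make_deformation(VolumeGeometry(structural.shape, (1.0, 1.0)),
                                    4.0, seed=11)
        S = warp_image(structural, field)
        pair = syn_register(S, structural, levels=(4,), max_iter=60)
        trace = np.asarray(pair.metric_trace)
        assert np.all(np.diff(trace) >= -1e-12)

    def test_recovers_known_deformation(self, phantom_128):
        _, atlas, structural = phantom_128
        field, landmarks = make_deformation(atlas.geometry, 5.0, seed=12)
        S = warp_image(structural, field)
        pair = syn_register(S, structural)

        def sample(d, pts):
            return np.stack([map_coordinates(c, pts.T, order=1, mode="nearest")
                             for c in d], axis=1)

        pts2 = landmarks + sample(pair.forward.disp, landmarks)
        err = np.linalg.norm(pts2 + sample(field.disp, pts2) - landmarks, axis=1)
        assert err.mean() <= 1.0
        assert jacobian_determinant(pair.forward).min() > 0
        assert jacobian_determinant(pair.inverse).min() > 0

    def test_inverse_consistency(self, phantom_128):
        _, atlas, structural = phantom_128
        field, _ = make_deformation(atlas.geometry, 5.0, seed=12)
        S = warp_image(structural, field)
        pair = syn_register(S, structural, levels=(4, 2), max_iter=60)
        comp = compose_fields(pair.forward.disp, pair.inverse.disp)
        assert np.mean(np.linalg.norm(comp, axis=0)) <= 0.05

    def test_three_dimensional_registration_improves_alignment(self):
        from neuropet.phantom import default_spec, make_phantom
        spec = default_spec(shape=(32, 32, 32), noise_percent=2.0, seed=0)
        atlas, structural = make_phantom(spec)
        field, _ = make_deformation(atlas.geometry, 2.0, smoothness_voxels=5.0, seed=2)
        S = warp_image(structural, field)
        pair = syn_register(S, structural, levels=(4, 2), max_iter=40, radius=2)
        before = np.abs(S - structural).mean()
        after = np.abs(warp_image(S, pair.forward.disp) - structural).mean()
        assert after < before
        assert jacobian_determinant(pair.forward).min() > 0


class TestCostFunctionMasking:
    def test_empty_mask_is_identity(self):
        u = np.random.default_rng(0).normal(size=(2, 16, 16))
        out = apply_cost_mask(u, np.zeros((16, 16), bool))
        np.testing.assert_array_equal(out, u)

    def test_constant_exterior_extends_exactly(self):
        u = np.full((2, 32, 32), 1.5)
        m = np.zeros((32, 32), bool)
        m[10:20, 12:22] = True
        out = apply_cost_mask(u, m)
        np.testing.assert_allclose(out, 1.5, atol=1e-10)

    def test_full_mask_rejected(self):
        with pytest.raises(ValueError):
            apply_cost_mask(np.zeros((2, 8, 8)), np.ones((8, 8), bool))

    def test_lesion_intensities_cannot_influence_registration(self, phantom_128):
        _, atlas, structural = phantom_128
        field, _ = make_deformation(atlas.geometry, 4.0, seed=13)
        S0 = warp_image(structural, field)
        S1, mask = insert_lesion(S0, (40, 40), (9, 7), 300.0)
        rng = np.random.default_rng(14)
        S2 = S1.copy()
        S2[mask] = rng.uniform(0, 400, int(mask.sum()))
        p1 = syn_register(S1, structural, levels=(4, 2), max_iter=40, mask=mask)
        p2 = syn_register(S2, structural, levels=(4, 2), max_iter=40, mask=mask)
        assert np.array_equal(p1.forward.disp, p2.forward.disp)
        assert np.array_equal(p1.inverse.disp, p2.inverse.disp)
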