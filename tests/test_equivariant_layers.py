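"""The three group-convolution operators and their equivariance contracts."""

import numpy as np
import pytest

from icodwi.equivariant_layers import (
    FiberKernel,
    SpatialKernel,
    StarKernel,
    gconv_so3,
    lift_s2,
    project_max,
    rotate_spatial_kernel,
    rotation_operator,
    spatial_conv,
)
from icodwi.icosa_group import (
    coordinate_axis_twofold_rotations,
    left_translate,
    stabilizer_cycle,
)
from icodwi.train_eval import rotate_grid_exact


def _rand_star(rng, ci=1, co=3):
    return StarKernel(weights=rng.normal(size=(ci, co, 11)),
                      bias=rng.normal(size=co))


def _rand_fiber(rng, ci, co):
    return FiberKernel(weights=rng.normal(size=(ci, co, 5)),
                       bias=rng.normal(size=co))


def _rand_spatial(rng, ci, co):
    return SpatialKernel(weights=rng.normal(size=(ci, co, 3, 3, 3)),
                         bias=rng.normal(size=co))


class TestStarLayout:
    def test_eleven_points_center_plus_two_rings(self, layout, ico):
        pts = layout.sample_points
        assert pts.shape == (11, 3)
        assert np.abs(np.linalg.norm(pts, axis=1) - 1).max() < 1e-12
        assert np.allclose(pts[0], ico.v0)
        # outer ring is the one-ring of v0
        assert np.allclose(pts[6:], ico.vertices[ico.neighbors[0]])

    def test_stabilizer_permutes_layout_cyclically(self, group, layout):
        cyc = stabilizer_cycle(group).rotations
        sigma1 = group.elements[cyc[1]]
        rotated = layout.sample_points @ sigma1.T
        # center fixed; each ring maps onto itself as a set, shifted by one arm
        assert np.linalg.norm(rotated[0] - layout.sample_points[0]) < 1e-9
        for lo, hi in ((1, 6), (6, 11)):
            ring = layout.sample_points[lo:hi]
            for p in rotated[lo:hi]:
                assert np.linalg.norm(ring - p, axis=1).min() < 1e-9

    def test_orbit_has_42_points(self, orbit):
        # 12 vertices + 30 edge arc-midpoints
        assert len(orbit.points) == 42
        assert orbit.index.shape == (60, 11)
        assert orbit.index.max() == 41


class TestLiftS2:
    def test_delta_center_kernel_reads_value_at_rotated_vertex(self, group, orbit):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(3, 1, 42))
        w = np.zeros((1, 1, 11))
        w[0, 0, 0] = 1.0
        out = lift_s2(vals, StarKernel(weights=w, bias=np.zeros(1)), group, orbit)
        for g in range(60):
            assert np.allclose(out[:, g, 0], vals[:, 0, orbit.index[g, 0]])

    def test_constant_input_gives_weight_sum_plus_bias(self, group, orbit):
        rng = np.random.default_rng(1)
        k = _rand_star(rng, ci=2, co=3)
        vals = np.full((2, 2, 42), 1.7)
        out = lift_s2(vals, k, group, orbit)
        expected = 1.7 * k.weights.sum(axis=(0, 2)) + k.bias
        assert np.abs(out - expected).max() < 1e-9

    def test_exact_equivariance_under_all_60_rotations(self, group, orbit,
                                                       orbit_perms):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(4, 1, 42))
        k = _rand_star(rng)
        out = lift_s2(vals, k, group, orbit)
        for h in range(60):
            rotated_in = vals[..., orbit_perms[h]]
            lhs = lift_s2(rotated_in, k, group, orbit)
            rhs = left_translate(group, h, out, axis=-2)
            assert np.abs(lhs - rhs).max() <= 1e-6 * max(1, np.abs(rhs).max())

    def test_wrong_orbit_size_rejected(self, group, orbit):
        with pytest.raises(ValueError):
            lift_s2(np.zeros((1, 1, 41)), _rand_star(np.random.default_rng(0)),
                    group, orbit)


class TestGconvSO3:
    def test_delta_identity_kernel_is_identity_map(self, group):
        rng = np.random.default_rng(3)
        F = rng.normal(size=(2, 60, 3))
        w = np.zeros((3, 3, 5))
        for c in range(3):
            w[c, c, 0] = 1.0
        out = gconv_so3(F, FiberKernel(weights=w, bias=np.zeros(3)), group)
        assert np.abs(out - F).max() < 1e-12

    def test_constant_feature_map_stays_constant(self, group):
        rng = np.random.default_rng(4)
        k = _rand_fiber(rng, 2, 4)
        F = np.full((3, 60, 2), 0.9)
        out = gconv_so3(F, k, group)
        expected = 0.9 * k.weights.sum(axis=(0, 2)) + k.bias
        assert np.abs(out - expected).max() < 1e-9

    def test_exact_left_equivariance_all_60(self, group):
        rng = np.random.default_rng(5)
        F = rng.normal(size=(3, 60, 4))
        k = _rand_fiber(rng, 4, 2)
        out = gconv_so3(F, k, group)
        scale = np.abs(out).max()
        for h in range(60):
            lhs = gconv_so3(left_translate(group, h, F, axis=-2), k, group)
            rhs = left_translate(group, h, out, axis=-2)
            assert np.abs(lhs - rhs).max() <= 1e-6 * scale

    def test_channel_mismatch_rejected(self, group):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            gconv_so3(np.zeros((1, 60, 3)), _rand_fiber(rng, 4, 2), group)


class TestRotateSpatialKernel:
    def test_identity_rotation_is_bit_exact(self):
        rng = np.random.default_rng(7)
        k = _rand_spatial(rng, 2, 3)
        rk = rotate_spatial_kernel(k, np.eye(3))
        assert np.array_equal(rk.weights, k.weights)

    @pytest.mark.parametrize("axis,flips", [
        (np.diag([1.0, -1, -1]), (slice(None), slice(None, None, -1),
                                  slice(None, None, -1))),
        (np.diag([-1.0, 1, -1]), (slice(None, None, -1), slice(None),
                                  slice(None, None, -1))),
        (np.diag([-1.0, -1, 1]), (slice(None, None, -1),
                                  slice(None, None, -1), slice(None))),
    ])
    def test_grid_exact_180_rotations_are_index_flips(self, axis, flips):
        rng = np.random.default_rng(8)
        k = _rand_spatial(rng, 1, 2)
        rk = rotate_spatial_kernel(k, axis)
        expected = k.weights[(slice(None), slice(None)) + flips]
        assert np.abs(rk.weights - expected).max() < 1e-12

    def test_central_weight_invariant_under_any_rotation(self, group):
        rng = np.random.default_rng(9)
        k = _rand_spatial(rng, 1, 1)
        for E in group.elements[::7]:
            rk = rotate_spatial_kernel(k, E)
            assert abs(rk.weights[0, 0, 1, 1, 1] - k.weights[0, 0, 1, 1, 1]) \
                < 1e-12

    def test_rotation_operator_rows_sum_to_at_most_one(self, group):
        # mass only leaks where corners rotate out of the support
        for E in group.elements[::11]:
            M = rotation_operator(E)
            assert M.min() >= 0
            assert M.sum(axis=1).max() <= 1 + 1e-12


class TestSpatialConv:
    def test_three_stacked_valid_convs_shrink_7_to_1(self, group):
        rng = np.random.default_rng(10)
        F = rng.normal(size=(7, 7, 7, 60, 2))
        for _ in range(3):
            k = _rand_spatial(rng, F.shape[-1], 2)
            F = spatial_conv(F, k, group, "none")
        assert F.shape == (1, 1, 1, 60, 2)

    def test_delta_kernel_crops_center_when_unrotated(self, group):
        rng = np.random.default_rng(11)
        F = rng.normal(size=(5, 5, 5, 60, 2))
        w = np.zeros((2, 2, 3, 3, 3))
        for c in range(2):
            w[c, c, 1, 1, 1] = 1.0
        k = SpatialKernel(weights=w, bias=np.zeros(2))
        out = spatial_conv(F, k, group, "none")
        assert np.abs(out - F[1:-1, 1:-1, 1:-1]).max() < 1e-9
        # in the rotated modes only identity-rotation slots crop exactly:
        # trilinear resampling of a rotated central delta leaks small weights
        # onto neighbouring offsets for non-grid rotations
        for mode, exact_slots in (("full", [0]), ("partial", range(5))):
            out = spatial_conv(F, k, group, mode)
            for g in exact_slots:
                assert np.abs(out[..., g, :]
                              - F[1:-1, 1:-1, 1:-1, g, :]).max() < 1e-9

    def test_full_mode_commutes_with_grid_exact_rotations(self, group):
        rng = np.random.default_rng(12)
        F = rng.normal(size=(5, 5, 5, 60, 2))
        k = _rand_spatial(rng, 2, 3)
        out = spatial_conv(F, k, group, "full")
        for h in coordinate_axis_twofold_rotations(group):
            R = group.elements[h]
            Fr = left_translate(group, h, rotate_grid_exact(F, R), axis=-2)
            lhs = spatial_conv(Fr, k, group, "full")
            rhs = left_translate(group, h, rotate_grid_exact(out, R), axis=-2)
            assert np.abs(lhs - rhs).max() <= 1e-9 * max(1, np.abs(rhs).max())

    def test_unrotated_mode_breaks_rotation_equivariance(self, group):
        # the contrast that motivates rotating the spatial kernel
        rng = np.random.default_rng(13)
        F = rng.normal(size=(5, 5, 5, 60, 2))
        k = _rand_spatial(rng, 2, 3)
        out = spatial_conv(F, k, group, "none")
        h = coordinate_axis_twofold_rotations(group)[0]
        R = group.elements[h]
        Fr = left_translate(group, h, rotate_grid_exact(F, R), axis=-2)
        lhs = spatial_conv(Fr, k, group, "none")
        rhs = left_translate(group, h, rotate_grid_exact(out, R), axis=-2)
        assert np.abs(lhs - rhs).max() > 0.01

    def test_too_small_input_rejected(self, group):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError):
            spatial_conv(np.zeros((2, 5, 5, 60, 1)),
                         _rand_spatial(rng, 1, 1), group, "none")


class TestProjectMax:
    def test_constant_map_projects_to_same_constant(self, group):
        F = np.full((2, 60, 3), 1.23)
        assert np.abs(project_max(F, group, "space") - 1.23).max() < 1e-12
        assert np.abs(project_max(F, group, "sphere") - 1.23).max() < 1e-12

    def test_space_matches_brute_force_max(self, group):
        rng = np.random.default_rng(15)
        F = rng.normal(size=(4, 60, 3))
        out = project_max(F, group, "space")
        for v in range(4):
            for c in range(3):
                assert out[v, c] == max(F[v, g, c] for g in range(60))

    def test_sphere_invariant_to_per_fiber_spin_permutations(self, group):
        rng = np.random.default_rng(16)
        F = rng.normal(size=(3, 60, 2))
        out = project_max(F, group, "sphere")
        shuffled = F.reshape(3, 12, 5, 2)[:, :, rng.permutation(5), :]
        out2 = project_max(shuffled.reshape(3, 60, 2), group, "sphere")
        assert np.array_equal(out, out2)

    def test_space_projection_invariant_under_left_translation(self, group):
        rng = np.random.default_rng(17)
        F = rng.normal(size=(2, 60, 3))
        out = project_max(F, group, "space")
        for h in range(60):
            out_h = project_max(left_translate(group, h, F, axis=-2),
                                group, "space")
            assert np.abs(out_h - out).max() <= 1e-6

    def test_sphere_projection_equivariant_via_vertex_permutation(self, group):
        rng = np.random.default_rng(18)
        F = rng.normal(size=(2, 60, 3))
        out = project_max(F, group, "sphere")  # (2, 12, 3)
        for h in (1, 13, 44):
            out_h = project_max(left_translate(group, h, F, axis=-2),
                                group, "sphere")
            assert np.abs(out_h[:, group.vertex_perm[h]] - out).max() <= 1e-9


def test_relu_interleaving_preserves_equivariance(group):
    """Pointwise nonlinearities between sublayers commute with the action."""
    rng = np.random.default_rng(19)
    F = rng.normal(size=(3, 60, 2))
    k = _rand_fiber(rng, 2, 2)
    out = np.maximum(gconv_so3(F, k, group), 0.0)
    for h in range(0, 60, 5):
        lhs = np.maximum(
            gconv_so3(left_translate(group, h, F, axis=-2), k, group), 0.0)
        rhs = left_translate(group, h, out, axis=-2)
        assert np.abs(lhs - rhs).max() <= 1e-9
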