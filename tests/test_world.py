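"""World geometry: retinotopic mapping, eye-frame transform, rasterization."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sacsim.world import (
    EyeRotation,
    Luminance,
    MappingParams,
    WorldRenderer,
    eye_frame_transform,
    forward_map,
    inverse_map,
    load_luminances,
    rotation_matrix,
)


class TestMappingParams:
    def test_foveal_magnification_closure(self, mapping):
        # M_f is fixed by requiring r(W_fov/2) = W_nfs exactly
        assert mapping.M_f == pytest.approx(
            mapping.W_nfs / (mapping.E2 * math.log(mapping.W_fov / (2 * mapping.E2) + 1))
        )
        r_edge, _ = forward_map(0.0, mapping.W_fov / 2.0, mapping)
        assert r_edge == pytest.approx(mapping.W_nfs, abs=1e-9)

    def test_magnification_halves_at_E2(self, mapping):
        assert mapping.magnification(mapping.E2) == pytest.approx(mapping.M_f / 2.0)


class TestForwardMap:
    def test_origin_maps_to_zero_radius(self):
        r, _ = forward_map(0.0, 0.0)
        assert r == 0.0

    @pytest.mark.parametrize(
        "tx,ty,phi_expected",
        [
            (10.0, 0.0, 1.0),     # up
            (0.0, 10.0, 13.5),    # left
            (-10.0, 0.0, 26.0),   # down
            (0.0, -10.0, 38.5),   # right
        ],
    )
    def test_cardinal_direction_anchors(self, tx, ty, phi_expected):
        _, phi = forward_map(tx, ty)
        assert phi == pytest.approx(phi_expected)

    def test_edge_of_view_radius(self, mapping):
        r, _ = forward_map(-30.5, 0.0, mapping)
        assert r == pytest.approx(50.0, abs=1e-9)

    def test_out_of_view_marked_nan(self):
        r, phi = forward_map(0.0, 35.0)
        assert math.isnan(r) and math.isnan(phi)

    def test_radius_increases_with_eccentricity(self):
        ecc = np.linspace(0.1, 30.0, 200)
        r, _ = forward_map(ecc, np.zeros_like(ecc))
        assert np.all(np.diff(r) > 0)

    def test_phi_wraps_around_up(self):
        # infinitesimally counter-clockwise vs clockwise of straight up
        _, phi_ccw = forward_map(10.0, 1e-6)
        _, phi_cw = forward_map(10.0, -1e-6)
        assert phi_ccw == pytest.approx(1.0, abs=1e-3)
        assert phi_cw == pytest.approx(51.0, abs=1e-3)


class TestInverseMap:
    def test_zero_radius_maps_to_origin(self):
        assert inverse_map(0.0, 17.0) == (0.0, 0.0)

    def test_edge_down(self, mapping):
        tx, ty = inverse_map(50.0, 26.0, mapping)
        assert tx == pytest.approx(-30.5, abs=1e-9)
        assert ty == pytest.approx(0.0, abs=1e-9)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            inverse_map(-1.0, 1.0)

    def test_round_trip_over_random_directions(self, rng):
        ecc = rng.uniform(0.01, 30.4, 1000)
        ang = rng.uniform(0.0, 2 * np.pi, 1000)
        tx, ty = ecc * np.cos(ang), ecc * np.sin(ang)
        r, phi = forward_map(tx, ty)
        tx2, ty2 = inverse_map(r, phi)
        assert np.max(np.hypot(tx2 - tx, ty2 - ty)) < 1e-6


class TestEyeFrameTransform:
    def test_identity_rotation(self):
        out = eye_frame_transform([(5.0, -10.0)], EyeRotation())
        assert out[0] == pytest.approx([5.0, -10.0])

    def test_foveated_target_maps_to_origin(self):
        out = eye_frame_transform([(7.0, -17.0)], EyeRotation(7.0, -17.0, 0.0))
        assert np.allclose(out[0], 0.0, atol=1e-9)

    def test_matches_rotation_matrix_oracle(self):
        # independent oracle: compose the two 3-D rotation matrices directly
        eye = EyeRotation(0.0, -10.0, 0.0)
        tgt = (7.0, -17.0)
        v = rotation_matrix(tgt[0], tgt[1]) @ np.array([0.0, 0.0, -1.0])
        v_eye = rotation_matrix(eye.theta_x, eye.theta_y, eye.theta_z).T @ v
        tx_o = math.degrees(math.atan2(v_eye[1], -v_eye[2]))
        ty_o = math.degrees(math.atan2(-v_eye[0], math.hypot(v_eye[1], v_eye[2])))
        out = eye_frame_transform([tgt], eye)[0]
        assert out == pytest.approx([tx_o, ty_o], abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tx=st.floats(-20, 20), ty=st.floats(-20, 20),
        ex=st.floats(-15, 15), ey=st.floats(-15, 15), ez=st.floats(-10, 10),
    )
    def test_round_trip_through_inverse_rotation(self, tx, ty, ex, ey, ez):
        eye = EyeRotation(ex, ey, ez)
        fwd = eye_frame_transform([(tx, ty)], eye)[0]
        # rotate the eye-frame angles back into the world
        v_eye = rotation_matrix(fwd[0], fwd[1]) @ np.array([0.0, 0.0, -1.0])
        v_world = eye.matrix() @ v_eye
        tx2 = math.degrees(math.atan2(v_world[1], -v_world[2]))
        ty2 = math.degrees(math.atan2(-v_world[0], math.hypot(v_world[1], v_world[2])))
        assert (tx2, ty2) == pytest.approx((tx, ty), abs=1e-9)


class TestLuminance:
    def test_validation(self):
        with pytest.raises(ValueError):
            Luminance(0, 0, magnitude=-0.1)
        with pytest.raises(ValueError):
            Luminance(0, 0, t_on=1.0, t_off=0.5)

    def test_activity_window_half_open(self):
        lum = Luminance(0, 0, t_on=0.1, t_off=0.5)
        assert not lum.active(0.0) and lum.active(0.1) and not lum.active(0.5)

    def test_load_world_config(self, tmp_path):
        path = tmp_path / "luminances.json"
        path.write_text(json.dumps([
            {"thetaX": 0, "thetaY": 0, "shape": "cross", "span": 3, "barWidth": 2,
             "magnitude": 0.2, "tOn": 0, "tOff": 0.4},
            {"thetaX": 0, "thetaY": -10, "magnitude": 0.3, "tOn": 0.4},
        ]))
        lums = load_luminances(path)
        assert len(lums) == 2
        assert lums[0].magnitude == 0.2 and lums[0].t_off == 0.4
        assert lums[1].theta_y == -10 and math.isinf(lums[1].t_off)


class TestRenderer:
    def test_empty_world_gives_zero_grid(self, renderer):
        grid = renderer.render([], EyeRotation(), 0.0)
        assert grid.shape == (50, 50) and not grid.any()

    def test_inactive_luminance_ignored(self, renderer):
        lum = Luminance(0, -10, magnitude=0.5, t_on=1.0)
        assert not renderer.render([lum], EyeRotation(), 0.5).any()

    def test_grid_nonnegative(self, renderer):
        grid = renderer.render([Luminance(0, -10, magnitude=0.5)], EyeRotation(), 0.0)
        assert np.all(grid >= 0.0)

    def test_foveal_target_activates_large_comb(self, renderer):
        # a foveated cross excites roughly one third of the map (pre-mask)
        grid = renderer.render([Luminance(0, 0, magnitude=0.8)], EyeRotation(), 0.0,
                               mask_fovea=False)
        frac = (grid > 0.01).mean()
        assert 0.2 < frac < 0.5

    def test_foveal_mask_zeroes_centre(self, renderer):
        grid = renderer.render([Luminance(0, 0, magnitude=0.8)], EyeRotation(), 0.0)
        assert not grid[renderer.cell_ecc < renderer.fovea_mask_deg].any()

    def test_peripheral_cross_lands_at_mapped_locus(self, renderer):
        grid = renderer.render([Luminance(0, -12, magnitude=0.5)], EyeRotation(), 0.0)
        r_idx, phi_idx = np.unravel_index(np.argmax(grid), grid.shape)
        r_exp, phi_exp = forward_map(0.0, -12.0)
        assert abs((r_idx + 1) - r_exp) <= 1.5
        assert abs((phi_idx + 1) - phi_exp) <= 1.5

    def test_rendering_equivariance_under_foveation(self, renderer):
        # rotating the eye exactly onto the target moves its activity
        # into the low-r region (all masked out by the fovea)
        lum = Luminance(4.0, -9.0, magnitude=0.5)
        foveated = renderer.render([lum], EyeRotation(4.0, -9.0, 0.0), 0.0)
        unmasked = renderer.render([lum], EyeRotation(4.0, -9.0, 0.0), 0.0,
                                   mask_fovea=False)
        assert unmasked.sum() > 0
        assert foveated.sum() < unmasked.sum()
        r_idx, _ = np.unravel_index(np.argmax(unmasked), unmasked.shape)
        assert r_idx + 1 < 10  # low-r comb

    def test_invariance_under_common_x_rotation(self, renderer):
        # rotating eye and target by the same angle about x leaves the
        # retinotopic image unchanged (x is the innermost Euler axis)
        lum0 = Luminance(2.0, -10.0, magnitude=0.5)
        lum1 = Luminance(2.0 + 6.0, -10.0, magnitude=0.5)
        g0 = renderer.render([lum0], EyeRotation(), 0.0)
        g1 = renderer.render([lum1], EyeRotation(6.0, 0.0, 0.0), 0.0)
        assert np.allclose(g0, g1, atol=1e-9)

    def test_overlap_combines_by_maximum(self, renderer):
        a = Luminance(0, -10, magnitude=0.3)
        b = Luminance(0, -10, magnitude=0.8)
        grid = renderer.render([a, b], EyeRotation(), 0.0, blur=False)
        assert grid.max() == pytest.approx(0.8)

    def test_sum_combination_configurable(self, mapping):
        ren = WorldRenderer(mapping, combine="sum", blur_sigma=0.0)
        a = Luminance(0, -10, magnitude=0.3)
        grid = ren.render([a, a], EyeRotation(), 0.0, blur=False)
        assert grid.max() == pytest.approx(0.6)
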