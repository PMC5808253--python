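"""Projection-kernel builders: edge lists, analytic oracles, weight maps."""

import math

import numpy as np
import pytest

from sacsim.connectivity import (
    CHANNEL_PHI,
    ProjectionSpec,
    WeightMapParams,
    WideningParams,
    build_decaying_at_fovea,
    build_diffuse,
    build_gaussian_kernel,
    build_one_to_one,
    build_sbg_weight_map,
    build_tecto_tectal_inhibition,
    build_widening_gaussian,
    fovea_decay_profile,
    widening_sigma,
)
from sacsim.world import MappingParams

N = 2500


def dense_oracle(spec: ProjectionSpec) -> np.ndarray:
    """Independent dense matrix assembled from the explicit edge list."""
    W = np.zeros((spec.n_target, spec.n_source))
    edges = spec.edges()
    np.add.at(W, (edges["tgt"].to_numpy(), edges["src"].to_numpy()),
              edges["weight"].to_numpy())
    return W


class TestOneToOne:
    def test_identity_pattern(self, rng):
        spec = build_one_to_one(N, 0.7)
        x = rng.random(N)
        assert np.allclose(spec.apply(x), 0.7 * x)

    def test_size_mismatch_rejected(self):
        spec = build_one_to_one(10, 1.0)
        with pytest.raises(ValueError):
            spec.apply(np.ones(11))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            build_one_to_one(5, -1.0)


class TestGaussianKernel:
    def test_self_edge_has_peak_weight(self):
        spec = build_gaussian_kernel(sigma=1.0, w_max=0.5)
        mat = spec.matrix
        assert mat[1275, 1275] == pytest.approx(0.5)

    def test_threshold_respected(self):
        spec = build_gaussian_kernel(sigma=1.2, w_max=1.0, threshold=0.05)
        assert spec.matrix.data.min() >= 0.05

    def test_axial_neighbours_equal(self):
        spec = build_gaussian_kernel(sigma=1.0, w_max=1.0)
        mat = spec.matrix.tocsc()
        src = 25 * 50 + 25  # central cell
        col = mat[:, src].toarray().ravel()
        neigh = [src + 50, src - 50, src + 1, src - 1]  # +-r, +-phi
        vals = col[neigh]
        assert np.allclose(vals, vals[0])

    def test_matches_dense_oracle_on_random_activity(self, rng):
        spec = build_gaussian_kernel(sigma=1.5, w_max=1.0)
        x = rng.random(N)
        assert np.allclose(spec.apply(x), dense_oracle(spec) @ x, atol=1e-12)

    def test_phi_axis_wraps(self):
        spec = build_gaussian_kernel(sigma=1.0, w_max=1.0)
        mat = spec.matrix.tocsc()
        src = 25 * 50 + 0  # phi = 1
        col = mat[:, src].toarray().ravel()
        assert col[25 * 50 + 49] > 0  # neighbour across the wrap


class TestDiffuse:
    def test_sums_source_activity(self, rng):
        spec = build_diffuse(N, N, 0.001)
        x = rng.random(N)
        out = spec.apply(x)
        assert np.allclose(out, 0.001 * x.sum())

    def test_permutation_invariance(self, rng):
        spec = build_diffuse(100, 100, 0.01)
        x = rng.random(100)
        assert np.allclose(spec.apply(x), spec.apply(rng.permutation(x)))

    def test_single_active_source(self):
        spec = build_diffuse(50, 50, 0.3)
        x = np.zeros(50)
        x[17] = 1.0
        assert np.allclose(spec.apply(x), 0.3)

    def test_edge_list_equivalent_to_sum_node(self, rng):
        spec = build_diffuse(30, 30, 0.2)
        x = rng.random(30)
        assert np.allclose(dense_oracle(spec) @ x, spec.apply(x), atol=1e-12)


class TestDecayingAtFovea:
    def test_profile_is_s_shaped(self):
        r = np.arange(1, 51, dtype=float)
        g = fovea_decay_profile(r)
        assert np.all(np.diff(g) > 0)
        # curvature changes sign exactly once (ignore flat numerical tails)
        curv = np.diff(g, 2)
        sign = np.sign(curv[np.abs(curv) > 1e-9])
        assert np.sum(np.diff(sign) != 0) == 1

    def test_limits(self):
        assert fovea_decay_profile(0.0) < 0.01
        assert fovea_decay_profile(50.0) > 0.99

    def test_periphery_weight_close_to_one(self):
        spec = build_decaying_at_fovea()
        mat = spec.matrix
        far = mat[49 * 50 + 10, 49 * 50 + 10]
        assert far == pytest.approx(1.0, abs=0.01)
        fovea = mat[10, 10]
        assert fovea <= far


class TestWidening:
    def test_sigma_constant_inside_fovea(self):
        assert widening_sigma(10.0) == pytest.approx(0.3)
        assert widening_sigma(20.0) == pytest.approx(0.3)

    def test_sigma_nondecreasing(self):
        r = np.linspace(0.0, 50.0, 400)
        sig = widening_sigma(r, WideningParams(m_sigma=2.0))
        assert np.all(np.diff(sig) >= -1e-12)
        assert np.all(sig >= 0.3)

    def test_zero_distance_weight_is_unity(self):
        spec = build_widening_gaussian(WideningParams(m_sigma=2.0))
        mat = spec.matrix
        assert mat[40 * 50 + 10, 40 * 50 + 10] == pytest.approx(1.0)

    def test_matches_dense_oracle(self, rng):
        spec = build_widening_gaussian(WideningParams(m_sigma=2.0))
        x = rng.random(N)
        assert np.allclose(spec.apply(x), dense_oracle(spec) @ x, atol=1e-12)

    def test_fanout_mass_grows_with_eccentricity(self):
        spec = build_widening_gaussian(WideningParams(m_sigma=2.0))
        mass = np.asarray(spec.matrix.sum(axis=0)).ravel()
        inner = mass[15 * 50 + 25]   # r = 16 (inside foveal region)
        outer = mass[45 * 50 + 25]   # r = 46
        assert outer > 3.0 * inner


class TestWeightMaps:
    def test_positive_half_sine_only(self):
        w = build_sbg_weight_map("left").reshape(50, 50)
        # "left" is centred at phi = 13.5; the rightward half-map is silent
        assert not w[:, 27:49].any()
        assert w[:, 12].all()

    def test_left_right_supports_disjoint(self):
        wl = build_sbg_weight_map("left")
        wr = build_sbg_weight_map("right")
        assert not np.any((wl > 0) & (wr > 0))

    def test_exponential_ratio_along_centre_line(self):
        params = WeightMapParams(i=0.0016, j=0.067)
        w = build_sbg_weight_map("right", params).reshape(50, 50)
        col = 37  # phi = 38 (closest column to the centre line 38.5)
        r1, r2 = 10, 30
        assert w[r2 - 1, col] / w[r1 - 1, col] == pytest.approx(
            math.exp(0.067 * (r2 - r1)), rel=1e-9
        )

    def test_matches_direct_evaluation(self):
        # brute-force evaluation of w = i e^{jr} sin_+(2 pi (phi-1)/50 + k)
        params = WeightMapParams(i=0.0016, j=0.067)
        w = build_sbg_weight_map("left", params)
        phi_c = CHANNEL_PHI["left"]
        k = math.pi / 2 - 2 * math.pi * (phi_c - 1) / 50.0
        expected = np.empty(2500)
        idx = 0
        for r in range(1, 51):
            for phi in range(1, 51):
                s = math.sin(2 * math.pi * (phi - 1) / 50.0 + k)
                expected[idx] = 0.0016 * math.exp(0.067 * r) * max(0.0, s)
                idx += 1
        assert np.allclose(w, expected, atol=1e-15)

    def test_oblique_maps_are_tenth_of_vertical(self):
        assert np.allclose(build_sbg_weight_map("z_plus"),
                           0.1 * build_sbg_weight_map("down"))
        assert np.allclose(build_sbg_weight_map("z_minus"),
                           0.1 * build_sbg_weight_map("up"))

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            build_sbg_weight_map("sideways")


class TestTectoTectal:
    def test_opposite_hemifield_target(self):
        spec = build_tecto_tectal_inhibition(gain=0.5)
        mat = spec.matrix.tocsc()
        src = 20 * 50 + 12  # phi = 13 (left hemifield)
        col = mat[:, src].toarray().ravel()
        assert col[20 * 50 + (12 + 25)] == pytest.approx(0.5)

    def test_inhibition_is_mutual(self):
        spec = build_tecto_tectal_inhibition(gain=0.5)
        mat = spec.matrix
        assert (abs(mat - mat.T)).max() < 1e-12

    def test_sign_is_inhibitory(self):
        assert build_tecto_tectal_inhibition(gain=0.1).sign == -1

    def test_gaussian_spread_variant(self, rng):
        spec = build_tecto_tectal_inhibition(gain=0.5, sigma=2.0)
        x = rng.random(N)
        assert np.allclose(spec.apply(x), dense_oracle(spec) @ x, atol=1e-12)
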