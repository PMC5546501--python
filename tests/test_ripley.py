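import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanoclust import (
    PointPattern,
    RGrid,
    Window,
    edge_correction_weight,
    k_function,
    l_transform,
    simulate_csr,
)
from nanoclust.ripley import KCurve

from oracles import brute_force_k, numeric_inside_fraction


class TestEdgeCorrectionWeight:
    def test_interior_circle_weight_is_one(self, window):
        assert edge_correction_weight((500, 500), 100, window) == pytest.approx(1.0)

    def test_edge_point_half_circle(self, window):
        assert edge_correction_weight((0, 500), 50, window) == pytest.approx(2.0)

    def test_corner_point_quarter_circle(self, window):
        assert edge_correction_weight((0, 0), 50, window) == pytest.approx(4.0)

    def test_matches_numeric_arc_integration(self, window, rng):
        pts = rng.uniform(0, 1000, size=(60, 2))
        radii = rng.uniform(1, 240, size=60)
        expected = 1.0 / numeric_inside_fraction(pts, radii, window)
        got = np.array([
            edge_correction_weight(tuple(p), r, window) for p, r in zip(pts, radii)
        ])
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_circle_wholly_outside_errors(self, window):
        with pytest.raises(ValueError, match="outside"):
            edge_correction_weight((500, 500), 5000, window)

    def test_invalid_inputs(self, window):
        with pytest.raises(ValueError):
            edge_correction_weight((500, 500), 0.0, window)
        with pytest.raises(ValueError):
            edge_correction_weight((1500, 500), 10, window)

    def test_cap_binds(self, window):
        w = edge_correction_weight((0, 0), 50, window, cap=3.0)
        assert w == 3.0


class TestKFunction:
    def test_far_apart_points_give_zero(self, window):
        pat = PointPattern([[100, 100], [600, 600], [100, 900]], window)
        curve = k_function(pat, correction="none")
        assert np.all(curve.k_values == 0)
        np.testing.assert_allclose(curve.l_values, -curve.rgrid.radii)

    def test_two_point_hand_value(self, window):
        # ordered pairs contribute twice: K = A * 2 / n^2 = 1e6 * 2/4
        pat = PointPattern([[475, 500], [525, 500]], window)
        curve = k_function(pat, correction="none")
        r = curve.rgrid.radii
        np.testing.assert_allclose(curve.k_values[r >= 50], 5e5)
        assert np.all(curve.k_values[r < 50] == 0)

    def test_matches_brute_force_none_exactly(self, window, coarse_grid, rng):
        for _ in range(5):
            pat = simulate_csr(rng.integers(5, 60), window, rng=rng)
            got = k_function(pat, coarse_grid, "none").k_values
            expected = brute_force_k(pat, coarse_grid.radii, "none")
            np.testing.assert_array_equal(got, expected)

    def test_matches_brute_force_isotropic(self, window, coarse_grid, rng):
        for _ in range(3):
            pat = simulate_csr(rng.integers(5, 40), window, rng=rng)
            got = k_function(pat, coarse_grid).k_values
            expected = brute_force_k(pat, coarse_grid.radii, "isotropic")
            np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_monotone_non_decreasing(self, window, rng):
        for _ in range(5):
            curve = k_function(simulate_csr(50, window, rng=rng))
            assert np.all(np.diff(curve.k_values) >= 0)

    def test_toroidal_wraps_distances(self):
        # points near opposite edges are 20 nm apart on the torus
        win = Window(1000, 1000)
        pat = PointPattern([[5, 500], [985, 500]], win)
        r = RGrid(np.array([10.0, 30.0]))
        curve = k_function(pat, r, "toroidal")
        assert curve.k_values[0] == 0
        assert curve.k_values[1] == pytest.approx(1e6 * 2 / 4)

    def test_scale_equivariance(self, window, rng):
        # K'(s r) = s^2 K(r) when coordinates and window both scale by s
        pat = simulate_csr(30, window, rng=rng)
        radii = np.array([10.0, 50.0, 120.0])
        base = k_function(pat, RGrid(radii)).k_values
        for s in (0.5, 3.0):
            scaled = PointPattern(pat.coords * s, Window(1000 * s, 1000 * s))
            ks = k_function(scaled, RGrid(radii * s)).k_values
            np.testing.assert_allclose(ks, s**2 * base, rtol=1e-10)

    def test_unbiased_denominator_variant(self, window, rng):
        pat = simulate_csr(20, window, rng=rng)
        k2 = k_function(pat, correction="none").k_values
        k1 = k_function(pat, correction="none", unbiased_n=True).k_values
        np.testing.assert_allclose(k1, k2 * 20 / 19, rtol=1e-12)

    def test_k_estimator_is_unbiased_for_csr(self, window, rng):
        # E[K(r)] = ((n-1)/n) pi r^2 with the n^-2 denominator
        n, sims = 100, 300
        radii = np.array([50.0, 100.0, 200.0])
        grid = RGrid(radii)
        ks = np.array([
            k_function(simulate_csr(n, window, rng=rng), grid).k_values
            for _ in range(sims)
        ])
        expected = (n - 1) / n * np.pi * radii**2
        z = (ks.mean(0) - expected) / (ks.std(0, ddof=1) / np.sqrt(sims))
        assert np.all(np.abs(z) < 3)

    def test_isotropic_reduces_edge_bias_at_large_r(self, window, rng):
        grid = RGrid(np.array([200.0]))
        l_iso, l_none = [], []
        for _ in range(150):
            pat = simulate_csr(200, window, rng=rng)
            l_iso.append(k_function(pat, grid, "isotropic").l_values[0])
            l_none.append(k_function(pat, grid, "none").l_values[0])
        assert abs(np.mean(l_iso)) < abs(np.mean(l_none))

    def test_errors(self, window):
        with pytest.raises(ValueError, match="at least 2"):
            k_function(PointPattern([[1, 1]], window))
        pat = PointPattern([[1, 1], [2, 2]], window)
        with pytest.raises(ValueError, match="correction"):
            k_function(pat, correction="bogus")


class TestLTransform:
    def test_csr_expectation_maps_to_zero(self):
        grid = RGrid()
        curve = KCurve(grid, np.pi * grid.radii**2)
        out = l_transform(curve)
        np.testing.assert_allclose(out.l_values, 0.0, atol=1e-9)

    def test_hand_value(self):
        grid = RGrid(np.array([50.0]))
        out = l_transform(KCurve(grid, np.array([5e5])))
        assert out.l_values[0] == pytest.approx(np.sqrt(5e5 / np.pi) - 50)
        assert out.l_values[0] == pytest.approx(348.94, abs=0.01)

    def test_zero_k_gives_minus_r(self):
        grid = RGrid(np.array([10.0]))
        out = l_transform(KCurve(grid, np.array([0.0])))
        assert out.l_values[0] == -10.0

    def test_negative_k_rejected(self):
        grid = RGrid(np.array([10.0]))
        with pytest.raises(ValueError):
            l_transform(KCurve(grid, np.array([-1.0])))


class TestRGrid:
    def test_default_grid_is_1_to_240(self):
        grid = RGrid()
        assert grid.radii[0] == 1.0 and grid.radii[-1] == 240.0 and len(grid) == 240

    @pytest.mark.parametrize("radii", [[0.0, 1.0], [2.0, 1.0], [1.0, 1.0], []])
    def test_invalid_grids(self, radii):
        with pytest.raises(ValueError):
            RGrid(np.array(radii))

    @given(st.floats(min_value=10, max_value=500), st.floats(min_value=0.5, max_value=5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_configurable_endpoints(self, r_max, step):
        grid = RGrid.default(r_max, step)
        assert grid.radii[0] == pytest.approx(step)
        assert grid.radii[-1] <= r_max + 1e-9
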