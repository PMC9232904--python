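"""Concomitant-field basis, dynamic coefficients, phase and field maps."""

import numpy as np
import pytest

import maxgirf as mg
from maxgirf.concomitant import (
    BASIS_MONOMIALS,
    ConcomitantModel,
    HigherOrderPhase,
    dynamic_coefficients,
    evaluate_basis,
    phase_coefficients,
    time_averaged_field_map,
)
from maxgirf.geometry import GAMMA_1H, FrameError, GradientSet, SpatialGrid


def _phys(samples):
    return GradientSet(np.asarray(samples, float), raster_s=1e-5, frame="physical")


def _grid_at(points):
    pts = np.atleast_2d(points)
    return SpatialGrid(
        shape=(pts.shape[0], 1), fov_m=(1.0, 1.0), coords=pts, frame="physical"
    )


class TestDynamicCoefficients:
    def test_zero_gradients_give_zero_coefficients(self):
        g = _phys(np.zeros((2, 8, 3)))
        h = dynamic_coefficients(g, ConcomitantModel(B0=0.55, order="full"))
        np.testing.assert_array_equal(h, 0.0)

    def test_x_gradient_drives_only_z2_term(self):
        g = np.zeros((1, 1, 3))
        g[..., 0] = 0.01
        h = dynamic_coefficients(_phys(g), ConcomitantModel(B0=0.55))
        # G = (10 mT/m, 0, 0) at 0.55 T: h6 = Gx^2 / 2 B0 = 1e-4 / 1.1
        np.testing.assert_allclose(h[0, 0, 2], 1e-4 / 1.1, rtol=1e-12)
        others = np.delete(h[0, 0], 2)
        np.testing.assert_array_equal(others, 0.0)

    def test_zero_z_gradient_leaves_only_z2_term(self, rng):
        g = rng.standard_normal((1, 16, 3)) * 0.02
        g[..., 2] = 0.0
        h = dynamic_coefficients(_phys(g), ConcomitantModel(B0=0.55))
        # terms 4, 5, 8, 9 all carry Gz; only h6 survives
        np.testing.assert_array_equal(h[..., [0, 1, 3, 4, 5]], 0.0)
        assert np.all(h[..., 2] > 0)

    def test_known_values_all_terms(self):
        gx, gy, gz, b0 = 0.01, -0.02, 0.015, 0.55
        g = np.array([[[gx, gy, gz]]])
        h = dynamic_coefficients(_phys(g), ConcomitantModel(B0=b0, order="full"))[0, 0]
        expected = {
            4: gz**2 / (8 * b0),
            5: gz**2 / (8 * b0),
            6: (gx**2 + gy**2) / (2 * b0),
            7: 0.0,
            8: -gy * gz / (2 * b0),
            9: -gx * gz / (2 * b0),
            10: -gx * gz**2 / (8 * b0**2),
            11: -gy * gz**2 / (8 * b0**2),
            12: -gz * (gx**2 + gy**2) / (2 * b0**2),
            13: -gy * gz**2 / (8 * b0**2),
            14: (gx**2 * gz - gz**3 / 4) / (2 * b0**2),
            15: -gx * gz**2 / (8 * b0**2),
            16: (gy**2 * gz - gz**3 / 4) / (2 * b0**2),
            17: -(gx * (gx**2 + gy**2) - gx * gz**2) / (2 * b0**2),
            18: -(gy * (gx**2 + gy**2) - gy * gz**2) / (2 * b0**2),
            19: gx * gy * gz / b0**2,
        }
        for j, l in enumerate(range(4, 20)):
            np.testing.assert_allclose(h[j], expected[l], rtol=1e-12, err_msg=f"term {l}")

    def test_quadratic_scaling_in_gradient_amplitude(self, rng):
        g = rng.standard_normal((1, 8, 3)) * 0.02
        model = ConcomitantModel(B0=0.55)
        h1 = dynamic_coefficients(_phys(g), model)
        h2 = dynamic_coefficients(_phys(2 * g), model)
        np.testing.assert_allclose(h2, 4 * h1, atol=1e-18)

    def test_field_strength_scaling(self, rng):
        """Halving B0 doubles the quadratic terms and quadruples the cubic."""
        g = rng.standard_normal((1, 8, 3)) * 0.02
        h_full = dynamic_coefficients(_phys(g), ConcomitantModel(B0=1.0, order="full"))
        h_half = dynamic_coefficients(_phys(g), ConcomitantModel(B0=0.5, order="full"))
        np.testing.assert_allclose(h_half[..., :6], 2 * h_full[..., :6], atol=1e-18)
        np.testing.assert_allclose(h_half[..., 6:], 4 * h_full[..., 6:], atol=1e-18)

    def test_logical_frame_rejected(self):
        g = GradientSet(np.zeros((1, 4, 3)), raster_s=1e-5, frame="logical")
        with pytest.raises(FrameError):
            dynamic_coefficients(g, ConcomitantModel(B0=0.55))


class TestPhaseCoefficients:
    def test_zero_in_zero_out(self):
        k = phase_coefficients(np.zeros((1, 10, 6)), np.arange(10) * 1e-5, GAMMA_1H)
        np.testing.assert_array_equal(k, 0.0)

    def test_constant_coefficient_integrates_linearly(self):
        times = np.arange(101) * 1e-5
        h = np.full((1, 101, 1), 3e-5)
        k = phase_coefficients(h, times, GAMMA_1H)
        np.testing.assert_allclose(k[0, :, 0], GAMMA_1H * 3e-5 * times, rtol=1e-12)

    def test_piecewise_constant_matches_antiderivative(self):
        times = np.arange(201) * 1e-5
        h = np.where(times < 1e-3, 2e-5, -1e-5)[None, :, None]
        k = phase_coefficients(h, times, GAMMA_1H)
        exact = GAMMA_1H * np.where(
            times <= 1e-3, 2e-5 * times, 2e-5 * 1e-3 - 1e-5 * (times - 1e-3)
        )
        # trapezoid straddles the jump by half a raster step
        np.testing.assert_allclose(k[0, :, 0], exact, atol=GAMMA_1H * 3e-5 * 1e-5)

    def test_starts_at_zero(self, rng):
        h = rng.standard_normal((2, 30, 6)) * 1e-5
        k = phase_coefficients(h, np.arange(30) * 1e-5, GAMMA_1H)
        np.testing.assert_array_equal(k[:, 0, :], 0.0)


class TestBasis:
    def test_origin_evaluates_to_zero(self):
        basis = evaluate_basis(_grid_at([0.0, 0.0, 0.0]), ConcomitantModel(B0=1.0, order="full"))
        np.testing.assert_array_equal(basis, 0.0)

    def test_monomial_arithmetic(self):
        basis = evaluate_basis(
            _grid_at([0.1, 0.2, 0.3]), ConcomitantModel(B0=1.0, order="full")
        )[0]
        terms = dict(zip(range(4, 20), basis))
        np.testing.assert_allclose(terms[4], 0.01)   # x^2
        np.testing.assert_allclose(terms[8], 0.06)   # yz
        np.testing.assert_allclose(terms[19], 0.006)  # xyz
        np.testing.assert_allclose(terms[12], 0.027)  # z^3

    def test_parity_under_point_reflection(self, rng):
        pts = rng.standard_normal((5, 3)) * 0.1
        model = ConcomitantModel(B0=1.0, order="full")
        plus = evaluate_basis(_grid_at(pts), model)
        minus = evaluate_basis(_grid_at(-pts), model)
        for j, l in enumerate(model.terms):
            degree = sum(BASIS_MONOMIALS[l])
            sign = 1.0 if degree % 2 == 0 else -1.0
            np.testing.assert_allclose(minus[:, j], sign * plus[:, j], atol=1e-15)

    def test_logical_grid_rejected(self):
        grid = SpatialGrid.make((2, 2), (0.1, 0.1))
        with pytest.raises(FrameError):
            evaluate_basis(grid, ConcomitantModel(B0=1.0))

    def test_monomial_table_contents(self):
        assert BASIS_MONOMIALS[4] == (2, 0, 0)
        assert BASIS_MONOMIALS[7] == (1, 1, 0)
        assert BASIS_MONOMIALS[19] == (1, 1, 1)
        assert len(BASIS_MONOMIALS) == 16
        lowest = ConcomitantModel(B0=1.0, order="lowest").terms
        full = ConcomitantModel(B0=1.0, order="full").terms
        assert set(lowest) < set(full)


class TestFieldMap:
    def _phase(self, g_samples, grid_pts, b0=0.55, order="lowest"):
        g = _phys(g_samples)
        model = ConcomitantModel(B0=b0, order=order)
        h = dynamic_coefficients(g, model)
        k = phase_coefficients(h, g.times_s, GAMMA_1H)
        basis = evaluate_basis(_grid_at(grid_pts), model)
        return HigherOrderPhase(k_coeffs=k, basis_values=basis, times_s=g.times_s)

    def test_zero_phase_gives_zero_map(self):
        phase = self._phase(np.zeros((1, 11, 3)), [[0.1, 0.0, 0.2]])
        np.testing.assert_array_equal(time_averaged_field_map(phase, 1e-4), 0.0)

    def test_constant_coefficients_make_map_independent_of_duration(self):
        """With constant h the map is (gamma / 2 pi) sum_l h_l p_l for any T."""
        g = np.zeros((1, 11, 3))
        g[..., 0] = 0.012
        pts = [[0.05, -0.03, 0.1]]
        phase = self._phase(g, pts)
        T = 10 * 1e-5
        fmap = time_averaged_field_map(phase, T)
        h6 = 0.012**2 / (2 * 0.55)
        expected = GAMMA_1H / (2 * np.pi) * h6 * 0.1**2
        np.testing.assert_allclose(fmap[0], expected, rtol=1e-10)
        np.testing.assert_allclose(time_averaged_field_map(phase, 2 * T) , fmap / 2)

    def test_axial_slice_map_is_spatially_constant(self, rng):
        """No z-gradient, fixed z0: only the z^2 term survives and it is
        constant over the slice -- a pure receive-frequency shift."""
        g = rng.standard_normal((1, 64, 3)) * 0.02
        g[..., 2] = 0.0
        z0 = 0.07
        xy = rng.standard_normal((20, 2)) * 0.1
        pts = np.column_stack([xy, np.full(20, z0)])
        phase = self._phase(g, pts)
        fmap = time_averaged_field_map(phase, 63 * 1e-5)
        assert np.ptp(fmap) < 1e-9 * abs(fmap).max()

    def test_full_minus_lowest_shrinks_with_field_strength(self, rng):
        """Cubic terms carry 1/B0^2, so (full - lowest) phase falls off one
        power of B0 faster than the lowest-order phase."""
        g = rng.standard_normal((1, 32, 3)) * 0.03
        pts = rng.standard_normal((30, 3)) * 0.15
        ratios = []
        for b0 in [0.55, 1.5, 3.0, 7.0]:
            low = self._phase(g, pts, b0=b0, order="lowest")
            full = self._phase(g, pts, b0=b0, order="full")
            phi_low = low.phase_matrix(0)
            phi_full = full.phase_matrix(0)
            ratios.append(np.linalg.norm(phi_full - phi_low) / np.linalg.norm(phi_low))
        scaled = np.array(ratios) * np.array([0.55, 1.5, 3.0, 7.0])
        np.testing.assert_allclose(scaled, scaled[0], rtol=1e-10)


class TestAxialDegeneracy:
    def test_concomitant_phase_matrix_is_rank_one(self, rng):
        """G_z = 0 on a fixed-z slice: exp(-j sum k_l p_l) factorizes as a
        time-only phasor times a constant, hence numerical rank 1."""
        g = rng.standard_normal((1, 128, 3)) * 0.02
        g[..., 2] = 0.0
        model = ConcomitantModel(B0=0.55)
        gset = _phys(g)
        h = dynamic_coefficients(gset, model)
        k = phase_coefficients(h, gset.times_s, GAMMA_1H)
        xy = rng.standard_normal((50, 2)) * 0.1
        pts = np.column_stack([xy, np.full(50, 0.06)])
        basis = evaluate_basis(_grid_at(pts), model)
        phase = HigherOrderPhase(k_coeffs=k, basis_values=basis, times_s=gset.times_s)
        H = np.exp(-1j * phase.phase_matrix(0))
        s = np.linalg.svd(H, compute_uv=False)
        assert s[1] / s[0] < 1e-10
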