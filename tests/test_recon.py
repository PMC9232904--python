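"""Conjugate-phase and least-squares reconstruction, NRMSE, density weights."""

import numpy as np
import pytest
from scipy.sparse.linalg import LinearOperator, lsqr

import maxgirf as mg
from maxgirf.encoding import CoilMaps, EncodingOperator, KSpaceData
from maxgirf.recon import (
    conjugate_phase,
    density_weights,
    nrmse,
    solve_lsq,
    voronoi_weights,
)


class TestNRMSE:
    def test_identical_images_give_zero(self, rng):
        m = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        assert nrmse(m, m) == 0.0

    def test_zero_test_image_gives_one(self, rng):
        m = rng.standard_normal(50) + 1j
        np.testing.assert_allclose(nrmse(m, np.zeros(50)), 1.0)

    def test_relative_scaling(self, rng):
        m = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        np.testing.assert_allclose(nrmse(m, m * 1.01), 0.01, rtol=1e-10)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            nrmse(np.zeros(5), np.ones(5))

    def test_mask_restricts_comparison(self, rng):
        m = rng.standard_normal(20)
        t = m.copy()
        t[:10] += 100.0
        mask = np.arange(20) >= 10
        assert nrmse(m, t, mask=mask) == 0.0


class TestDensityWeights:
    def test_constant_speed_sampling_gives_constant_weights(self):
        """Uniformly spaced samples (Cartesian-equivalent raster line)."""
        n = 64
        k = np.zeros((1, n, 3))
        k[0, :, 0] = np.linspace(1.0, 100.0, n)
        traj = mg.Trajectory(k, times_s=np.arange(n) * 1e-5)
        w = density_weights(traj)
        np.testing.assert_allclose(w, 1.0, rtol=1e-9)

    def test_constant_angular_rate_spiral_weights_grow_like_radius(self):
        theta = np.linspace(0.0, 20 * np.pi, 2000)  # constant dtheta/dt
        a = 25.0
        k = np.zeros((1, theta.size, 3))
        k[0, :, 0] = a * theta * np.cos(theta)
        k[0, :, 1] = a * theta * np.sin(theta)
        traj = mg.Trajectory(k, times_s=np.arange(theta.size) * 1e-5)
        w = density_weights(traj)
        r = np.linalg.norm(k[0, :, :2], axis=1)
        sel = r > 0.1 * r.max()
        ratio = w[sel] / r[sel]
        assert np.std(ratio) / np.mean(ratio) < 0.01
        assert np.all(np.diff(w[sel]) >= -1e-9)

    def test_designed_spiral_weights_positive_and_monotone_in_core(self):
        g = mg.design_spiral(0.24, 0.24 / 32, 4)
        traj = mg.integrate_kspace(g, mg.ScanGeometry(np.eye(3)))
        w = density_weights(traj)
        assert np.all(w > 0)
        np.testing.assert_allclose(w.mean(), 1.0)
        # slew-limited core accelerates: weights rise along the readout there
        assert w[10] < w[100] <= w.max()

    def test_degenerate_trajectory_rejected(self):
        traj = mg.Trajectory(np.zeros((1, 8, 3)), times_s=np.arange(8) * 1e-5)
        with pytest.raises(ValueError, match="degenerate"):
            density_weights(traj)

    def test_voronoi_weights_positive_and_normalized(self):
        g = mg.design_spiral(0.24, 0.24 / 24, 3)
        traj = mg.integrate_kspace(g, mg.ScanGeometry(np.eye(3)))
        w = voronoi_weights(traj)
        assert np.all(w > 0)
        np.testing.assert_allclose(w.mean(), 1.0)

    def test_voronoi_agrees_with_analytic_on_spiral_body(self):
        g = mg.design_spiral(0.24, 0.24 / 24, 3)
        traj = mg.integrate_kspace(g, mg.ScanGeometry(np.eye(3)))
        wa = density_weights(traj)
        wv = voronoi_weights(traj)
        r = np.linalg.norm(traj.k_samples[0, :, :2], axis=1)
        sel = (r > 0.3 * r.max()) & (r < 0.9 * r.max())
        ratio = wv[sel] / wa[sel]
        assert np.std(ratio) / np.mean(ratio) < 0.2


def _cartesian_setup(rng, n=12, n_coils=1, phase=False):
    """Fully sampled Cartesian-equivalent trajectory on an n x n grid."""
    fov = 0.2
    grid = mg.SpatialGrid.make((n, n), (fov, fov))
    kv = 2 * np.pi * np.fft.fftfreq(n, d=fov / n)
    kx, ky = np.meshgrid(kv, kv, indexing="ij")
    k = np.zeros((1, n * n, 3))
    k[0, :, 0] = kx.ravel()
    k[0, :, 1] = ky.ravel()
    traj = mg.Trajectory(k, times_s=np.arange(n * n) * 2.5e-6)
    coil = (
        CoilMaps.uniform(grid.n_voxels)
        if n_coils == 1
        else mg.make_coilmaps(n_coils, grid)
    )
    ho_phase = None
    if phase:
        from maxgirf.concomitant import HigherOrderPhase

        deltaf = mg.make_offresonance(grid, 60.0)
        k_coeffs = np.zeros((1, n * n, 1))
        k_coeffs[0, :, 0] = np.linspace(0, 40.0, n * n)  # mild quadratic-term sweep
        basis = (grid.coords[:, 0] ** 2 + grid.coords[:, 1] ** 2)[:, None]
        ho_phase = HigherOrderPhase(
            k_coeffs=k_coeffs, basis_values=basis,
            times_s=traj.times_s, deltaf_Hz=deltaf,
        )
    op = EncodingOperator.build(
        traj, grid, coil, phase=ho_phase, mode="dense"
    )
    m = (rng.standard_normal(grid.n_voxels) + 1j * rng.standard_normal(grid.n_voxels))
    return op, m, traj


class TestConjugatePhase:
    def test_zero_data_gives_zero_image(self, rng):
        op, m, traj = _cartesian_setup(rng)
        data = KSpaceData(np.zeros((1, 1, traj.n_samples), complex), 2.5e-6)
        res = conjugate_phase(op, data, np.ones(traj.n_samples))
        np.testing.assert_array_equal(res.image, 0.0)

    def test_recovers_image_on_full_cartesian_sampling(self, rng):
        """H = 1, uniform coil, unit weights: the adjoint of an orthogonal
        DFT recovers the image up to the known factor N."""
        op, m, traj = _cartesian_setup(rng)
        data = KSpaceData(op.forward(m), 2.5e-6)
        res = conjugate_phase(op, data, np.ones(traj.n_samples))
        assert nrmse(m, res.image / traj.n_samples) < 1e-8

    def test_weight_validation(self, rng):
        op, m, traj = _cartesian_setup(rng)
        data = KSpaceData(op.forward(m), 2.5e-6)
        with pytest.raises(ValueError, match="positive"):
            conjugate_phase(op, data, -np.ones(traj.n_samples))
        with pytest.raises(ValueError, match="length"):
            conjugate_phase(op, data, np.ones(3))

    def test_end_to_end_spiral_quality(self, desk32):
        """Density-compensated adjoint on a Nyquist spiral: within 10% of the
        truth for a band-limited object (a sharp-edged phantom additionally
        carries the spiral-disk truncation floor, so it gets a looser bound)."""
        grid = mg.SpatialGrid.make((64, 64), (0.24, 0.24))
        x, y = grid.coords[:, 0], grid.coords[:, 1]
        smooth = np.exp(-(x**2 + y**2) / (2 * 0.05**2)).astype(complex)
        g = mg.design_spiral(0.24, 0.24 / 64, 6)
        geom = mg.axial_geometry(0.0)
        coil = CoilMaps.uniform(grid.n_voxels)
        data = mg.simulate_acquisition(smooth, coil, None, grid, geom, g)
        setup = mg.prepare_encoding(g, geom, grid, coil)
        res = mg.reconstruct(setup, data, method="cp")
        scale = np.vdot(res.image, smooth) / np.vdot(res.image, res.image)
        assert nrmse(smooth, res.image * scale) < 0.1

        sc = desk32
        setup = mg.prepare_encoding(
            sc.gradients, sc.geom, sc.grid, sc.coilmaps,
            deltaf_Hz=sc.deltaf_Hz, model=sc.model,
        )
        img = mg.reconstruct(setup, sc.data, method="cp").image
        scale = np.vdot(img, sc.truth) / np.vdot(img, img)
        assert nrmse(sc.truth, img * scale) < 0.25


class TestSolveLsq:
    def test_zero_data_stays_at_zero(self, rng):
        op, m, traj = _cartesian_setup(rng)
        data = KSpaceData(np.zeros((1, 1, traj.n_samples), complex), 2.5e-6)
        res = solve_lsq(op, data)
        np.testing.assert_array_equal(res.image, 0.0)
        assert res.iterations == 0

    def test_inverse_crime_recovery_with_higher_order_phase(self, rng):
        """Consistent noiseless data, full sampling, multi-coil, off-resonance
        and concomitant phase in the operator: 15 iterations recover the
        image to well under 0.1% NRMSE."""
        op, m, traj = _cartesian_setup(rng, n_coils=3, phase=True)
        data = KSpaceData(op.forward(m), 2.5e-6)
        res = solve_lsq(op, data, max_iter=15, tol=1e-5)
        assert nrmse(m, res.image) < 1e-3

    def test_residual_history_non_increasing(self, desk32):
        sc = desk32
        setup = mg.prepare_encoding(
            sc.gradients, sc.geom, sc.grid, sc.coilmaps,
            deltaf_Hz=sc.deltaf_Hz, model=sc.model,
        )
        res = mg.reconstruct(setup, sc.data, method="lsq")
        assert np.all(np.diff(res.residuals) <= 1e-9 * res.residuals[0])

    def test_matches_scipy_lsqr(self, rng):
        """Independent solver cross-check on the same stacked operator."""
        op, m, traj = _cartesian_setup(rng, n_coils=2, phase=True)
        b = op.forward(m)
        shape_d = b.shape

        A = LinearOperator(
            (b.size, op.n_voxels),
            matvec=lambda x: op.forward(x).ravel(),
            rmatvec=lambda y: op.adjoint(y.reshape(shape_d)),
            dtype=complex,
        )
        x_ref = lsqr(A, b.ravel(), iter_lim=30, atol=1e-12, btol=1e-12)[0]
        res = solve_lsq(op, KSpaceData(b, 2.5e-6), max_iter=30, tol=1e-12)
        assert nrmse(x_ref, res.image) < 1e-6

    def test_lsq_beats_conjugate_phase_on_undersampled_interleaves(self, desk32):
        """Iterative reconstruction suppresses the aliasing the adjoint
        leaves behind when single interleaves undersample."""
        sc = desk32
        setup = mg.prepare_encoding(
            sc.gradients, sc.geom, sc.grid, sc.coilmaps,
            deltaf_Hz=sc.deltaf_Hz, model=sc.model,
        )
        cp = mg.reconstruct(setup, sc.data, method="cp")
        lsq = mg.reconstruct(setup, sc.data, method="lsq")
        scale = np.vdot(cp.image, sc.truth) / np.vdot(cp.image, cp.image)
        assert nrmse(sc.truth, lsq.image) <= nrmse(sc.truth, cp.image * scale)


class TestSenseEquivalence:
    def test_maxgirf_reduces_to_sense_without_phase_terms(self, rng):
        """Zero off-resonance and disabled concomitant model: the solver
        output equals CG-SENSE (H = 1 operator) to solver tolerance."""
        sc = mg.desk_scenario(
            orientation="axial", offset_m=0.0, B0=0.55, matrix=24,
            n_interleaves=3, n_coils=3, concomitant_order=None,
        )
        setup_plain = mg.prepare_encoding(sc.gradients, sc.geom, sc.grid, sc.coilmaps)
        zero_df = np.zeros(sc.grid.n_voxels)
        setup_h1 = mg.prepare_encoding(
            sc.gradients, sc.geom, sc.grid, sc.coilmaps, deltaf_Hz=zero_df,
        )
        r1 = mg.reconstruct(setup_plain, sc.data, method="lsq")
        r2 = mg.reconstruct(setup_h1, sc.data, method="lsq")
        assert nrmse(r1.image, r2.image) < 1e-10
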