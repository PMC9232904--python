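import numpy as np
import pytest

import maxgirf as mg
from maxgirf.concomitant import ConcomitantModel, compute_higher_order_phase
from maxgirf.geometry import transform_to_physical


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    return q


@pytest.fixture
def random_rotation(rng):
    return _random_rotation(rng)


@pytest.fixture(scope="session")
def small_setup():
    """A 16x16, 2-interleaf, 3-coil encoding problem with off-resonance and
    full-order concomitant fields -- small enough for dense-matrix oracles."""
    matrix, fov = 16, 0.24
    geom = mg.sagittal_geometry(0.07, B0=0.55)
    grads = mg.design_spiral(fov, fov / matrix, 2)
    grid = mg.SpatialGrid.make((matrix, matrix), (fov, fov))
    coil = mg.make_coilmaps(3, grid)
    deltaf = mg.make_offresonance(grid, 120.0)
    model = ConcomitantModel(B0=geom.B0, order="full")
    g_phys = transform_to_physical(grads, geom)
    grid_P = transform_to_physical(grid, geom)
    phase = compute_higher_order_phase(g_phys, grid_P, geom, model, deltaf_Hz=deltaf)
    traj_L = mg.integrate_kspace(grads, geom)
    op = mg.EncodingOperator.build(traj_L, grid, coil, phase=phase, mode="dense")
    return {
        "geom": geom,
        "grads": grads,
        "grid": grid,
        "coil": coil,
        "deltaf": deltaf,
        "model": model,
        "phase": phase,
        "traj_L": traj_L,
        "op": op,
    }


@pytest.fixture(scope="session")
def desk32():
    """A quick 32x32 sagittal acquisition with concomitant fields."""
    return mg.desk_scenario(
        orientation="sagittal", offset_m=0.05, B0=0.55, matrix=32,
        n_interleaves=4, n_coils=3, deltaf_peak_Hz=100.0,
    )
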