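"""Ready-made desk-scale study conditions.

The default scenario mirrors the structure of the validation studies the
method was designed around, shrunk to sizes where the exact dense operators
run in seconds: a 64 x 64 matrix over a 240 mm field of view, a 6-interleaf
uniform-density spiral designed at 24 mT/m and 144 T/m/s with a 2.5 us ADC
dwell (~2.4 ms readout at this resolution), 4 receive coils, and 0.55 T.
Field-strength and off-isocenter sweeps vary only ``B0`` and the slice
offset.  Synthesis can run on a 2x finer grid than reconstruction
(``sim_oversample=2``) so that recovery is not an inverse crime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .concomitant import ConcomitantModel
from .encoding import CoilMaps, KSpaceData
from .geometry import (
    GradientSet,
    ScanGeometry,
    SpatialGrid,
    axial_geometry,
    oblique_sagittal_geometry,
    sagittal_geometry,
)
from .simulator import (
    Ellipse,
    NoiseModel,
    default_phantom_spec,
    make_coilmaps,
    make_offresonance,
    make_phantom,
    simulate_acquisition,
)
from .spiral import design_spiral

__all__ = ["DeskScenario", "desk_scenario", "rank_study_scenario", "rank_study"]


@dataclass
class DeskScenario:
    """A simulated acquisition plus the recon-grid ground truth."""

    data: KSpaceData
    gradients: GradientSet
    geom: ScanGeometry
    grid: SpatialGrid
    coilmaps: CoilMaps
    truth: np.ndarray
    deltaf_Hz: Optional[np.ndarray]
    model: Optional[ConcomitantModel]


def desk_scenario(
    orientation: str = "sagittal",
    offset_m: float = 0.0,
    B0: float = 0.55,
    matrix: int = 64,
    fov_m: float = 0.24,
    n_interleaves: int = 6,
    n_coils: int = 4,
    deltaf_peak_Hz: float = 0.0,
    fat_region: Optional[Ellipse] = None,
    concomitant_order: Optional[str] = "lowest",
    gmax_T_per_m: float = 24e-3,
    smax_T_per_m_s: float = 144.0,
    dwell_s: float = 2.5e-6,
    sim_oversample: int = 1,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DeskScenario:
    """Generate a complete synthetic spiral acquisition.

    ``concomitant_order`` of None disables concomitant fields entirely
    (useful for SENSE-equivalence checks); ``deltaf_peak_Hz = 0`` and no fat
    region disables static off-resonance.
    """
    if orientation == "axial":
        geom = axial_geometry(offset_m, B0)
    elif orientation == "sagittal":
        geom = sagittal_geometry(offset_m, B0)
    elif orientation == "oblique-sagittal":
        geom = oblique_sagittal_geometry(offset_m, B0=B0)
    else:
        raise ValueError("orientation must be 'axial', 'sagittal' or 'oblique-sagittal'")

    gradients = design_spiral(
        fov_m=fov_m,
        resolution_m=fov_m / matrix,
        n_interleaves=n_interleaves,
        gmax_T_per_m=gmax_T_per_m,
        smax_T_per_m_s=smax_T_per_m_s,
        dwell_s=dwell_s,
    )

    grid = SpatialGrid.make((matrix, matrix), (fov_m, fov_m))
    spec = default_phantom_spec(fov_m)
    truth = make_phantom(spec, grid)
    coils = make_coilmaps(n_coils, grid)
    want_df = deltaf_peak_Hz != 0.0 or fat_region is not None
    deltaf = (
        make_offresonance(grid, deltaf_peak_Hz, fat_region=fat_region) if want_df else None
    )
    model = ConcomitantModel(B0=B0, order=concomitant_order) if concomitant_order else None

    if sim_oversample > 1:
        m_f = matrix * sim_oversample
        grid_f = SpatialGrid.make((m_f, m_f), (fov_m, fov_m))
        phantom_f = make_phantom(spec, grid_f)
        coils_f = make_coilmaps(n_coils, grid_f)
        deltaf_f = (
            make_offresonance(grid_f, deltaf_peak_Hz, fat_region=fat_region) if want_df else None
        )
        # finer voxels carry less signal each; rescale so total signal matches
        phantom_f = phantom_f / sim_oversample**2
        data = simulate_acquisition(
            phantom_f, coils_f, deltaf_f, grid_f, geom, gradients, model,
            NoiseModel(noise_sigma, seed),
        )
    else:
        data = simulate_acquisition(
            truth, coils, deltaf, grid, geom, gradients, model,
            NoiseModel(noise_sigma, seed),
        )
    return DeskScenario(
        data=data,
        gradients=gradients,
        geom=geom,
        grid=grid,
        coilmaps=coils,
        truth=truth,
        deltaf_Hz=deltaf,
        model=model,
    )


def rank_study_scenario(
    orientation: str,
    offset_m: float = 0.05,
    B0: float = 0.55,
    deltaf_peak_Hz: float = 150.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> DeskScenario:
    """Conditions for the truncation-rank study.

    The rank needed by the concomitant phase grows with the square of the
    spatial coverage (the dominant term is quadratic in position) and with
    gradient amplitude, so the study runs where the method's rank behaviour
    is actually exercised: a single-shot 64 x 64 spiral over a 0.48 m
    sagittal head-and-neck-scale field of view at the scanner's hardware
    limits (45 mT/m, 200 T/m/s), giving a ~12.5 ms readout comparable to
    the multislice spin-echo scans such studies are run on.  The axial
    comparator is matched in every respect except orientation.
    """
    return desk_scenario(
        orientation=orientation,
        offset_m=offset_m,
        B0=B0,
        matrix=64,
        fov_m=0.48,
        n_interleaves=1,
        n_coils=4,
        deltaf_peak_Hz=deltaf_peak_Hz,
        gmax_T_per_m=45e-3,
        smax_T_per_m_s=200.0,
        dwell_s=1e-6,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def rank_study(
    scenario: DeskScenario,
    L_max: int = 40,
    threshold: float = 0.02,
    svd_seed: int = 1,
):
    """Rank-NRMSE curve of conjugate-phase reconstructions for one scenario.

    Returns ``(L_at_threshold, curve)`` where ``curve[L-1]`` is the NRMSE
    between the rank-L and the full-rank (dense-H) conjugate-phase images.
    """
    from .encoding import KSpaceData
    from .geometry import demodulate_offset
    from .pipeline import prepare_encoding
    from .recon import conjugate_phase, conjugate_phase_rank_images, density_weights, nrmse

    sc = scenario
    common = dict(deltaf_Hz=sc.deltaf_Hz, model=sc.model)
    dense = prepare_encoding(sc.gradients, sc.geom, sc.grid, sc.coilmaps, mode="dense", **common)
    dcf = density_weights(dense.traj_L)
    samples = sc.data.samples
    if np.any(sc.geom.offset_P != 0):
        samples = demodulate_offset(samples, dense.traj_P, sc.geom)
    data = KSpaceData(samples, sc.data.dwell_s)
    ref = conjugate_phase(dense.op, data, dcf).image
    del dense  # free the cached dense matrices before the SVD pass
    lowrank = prepare_encoding(
        sc.gradients, sc.geom, sc.grid, sc.coilmaps, mode="lowrank", L_max=L_max,
        svd_seed=svd_seed, **common,
    )
    imgs = conjugate_phase_rank_images(lowrank.op, data, dcf)
    curve = np.array([nrmse(ref, im) for im in imgs])
    below = np.nonzero(curve < threshold)[0]
    L = int(below[0]) + 1 if below.size else L_max
    return L, curve
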