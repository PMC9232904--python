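"""End-to-end reconstruction flow tying the modules together.

transform -> GIRF-predict -> integrate -> concomitant/off-resonance phase ->
encoding operator (dense or low-rank) -> conjugate-phase or least-squares
reconstruction.  These functions are the library behind both the examples
and the command-line interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .concomitant import ConcomitantModel, HigherOrderPhase, compute_higher_order_phase
from .encoding import CoilMaps, EncodingOperator, KSpaceData
from .geometry import (
    GradientSet,
    ScanGeometry,
    SpatialGrid,
    Trajectory,
    demodulate_offset,
    integrate_kspace,
    transform_to_logical,
    transform_to_physical,
)
from .girf import GirfModel, predict_gradients
from .recon import ReconResult, conjugate_phase, density_weights, solve_lsq

__all__ = ["EncodingSetup", "prepare_encoding", "reconstruct"]


@dataclass
class EncodingSetup:
    """Everything derived from gradients + geometry that recon needs."""

    op: EncodingOperator
    traj_L: Trajectory
    traj_P: Trajectory
    phase: Optional[HigherOrderPhase]
    grid: SpatialGrid
    geom: ScanGeometry


def prepare_encoding(
    gradients_L: GradientSet,
    geom: ScanGeometry,
    grid_L: SpatialGrid,
    coilmaps: CoilMaps,
    deltaf_Hz: Optional[np.ndarray] = None,
    model: Optional[ConcomitantModel] = None,
    girf: Optional[GirfModel] = None,
    mode: str = "dense",
    L: Optional[int] = None,
    L_max: int = 50,
    svd_seed: int = 0,
) -> EncodingSetup:
    """Build the encoding operator from nominal logical-frame gradients.

    If a GIRF is supplied the nominal gradients are first transformed to the
    physical frame and filtered; the Fourier trajectory is then the
    *predicted* trajectory rotated back to the logical frame, and the
    concomitant coefficients are computed from the predicted physical
    gradients.  With ``model`` and ``deltaf_Hz`` both None the operator is a
    plain Fourier/SENSE operator (H = 1).
    """
    g_phys = transform_to_physical(gradients_L, geom)
    if girf is not None:
        g_phys = predict_gradients(g_phys, girf)
    traj_P = integrate_kspace(g_phys, geom)
    traj_L = transform_to_logical(traj_P, geom)

    phase = None
    if model is not None or deltaf_Hz is not None:
        grid_P = transform_to_physical(grid_L, geom)
        eff_model = model if model is not None else ConcomitantModel(B0=geom.B0)
        phase = compute_higher_order_phase(g_phys, grid_P, geom, eff_model, deltaf_Hz=deltaf_Hz)
        if model is None:
            phase.k_coeffs = np.zeros_like(phase.k_coeffs)
    op = EncodingOperator.build(
        traj_L, grid_L, coilmaps, phase=phase, mode=mode if phase is not None else "dense",
        L=L, L_max=L_max, svd_seed=svd_seed,
    )
    return EncodingSetup(op=op, traj_L=traj_L, traj_P=traj_P, phase=phase, grid=grid_L, geom=geom)


def reconstruct(
    setup: EncodingSetup,
    data: KSpaceData,
    method: str = "lsq",
    demodulate: bool = True,
    dcf: Optional[np.ndarray] = None,
    max_iter: int = 15,
    tol: float = 1e-5,
) -> ReconResult:
    """Reconstruct an image with the prepared encoding.

    ``method`` is ``"lsq"`` (iterative least squares) or ``"cp"`` (conjugate
    phase).  Raw off-isocenter data are slice-offset demodulated first
    unless ``demodulate=False`` (already-demodulated input).
    """
    samples = data.samples
    if demodulate and np.any(setup.geom.offset_P != 0):
        samples = demodulate_offset(samples, setup.traj_P, setup.geom)
    prepared = KSpaceData(samples=samples, dwell_s=data.dwell_s, noise_sigma=data.noise_sigma)
    if method == "lsq":
        return solve_lsq(setup.op, prepared, max_iter=max_iter, tol=tol)
    if method == "cp":
        if dcf is None:
            dcf = density_weights(setup.traj_L)
        return conjugate_phase(setup.op, prepared, dcf)
    raise ValueError("method must be 'lsq' or 'cp'")
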