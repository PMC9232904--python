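"""Image reconstruction: conjugate phase and iterative least squares.

Two estimators share the encoding-operator contract:

* ``conjugate_phase`` -- the adjoint operator applied to density-compensated
  data; non-iterative, needs approximate sample-density weights;
* ``solve_lsq`` -- minimizes ``sum_ic || d_ic - E_i S_c m ||^2`` with a
  conjugate-direction Krylov method on the normal equations (CGLS; the same
  iterate family as LSQR), defaults 15 iterations at tolerance 1e-5.

With the higher-order phase disabled (H = 1) the least-squares path reduces
to CG-SENSE, and with a single uniform coil the conjugate-phase path reduces
to a plain gridding/NUFFT-style reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .encoding import EncodingOperator, KSpaceData
from .geometry import Trajectory

__all__ = [
    "ReconResult",
    "nrmse",
    "density_weights",
    "voronoi_weights",
    "conjugate_phase",
    "solve_lsq",
]


@dataclass
class ReconResult:
    """A reconstructed image plus solver provenance."""

    image: np.ndarray
    method: str
    L: Optional[int] = None
    iterations: int = 0
    residuals: List[float] = field(default_factory=list)
    converged: bool = True


def nrmse(ref: np.ndarray, test: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Normalized RMS error ||ref - test|| / ||ref|| on complex values."""
    ref = np.asarray(ref).ravel()
    test = np.asarray(test).ravel()
    if ref.shape != test.shape:
        raise ValueError("ref and test must have the same length")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).ravel()
        ref, test = ref[mask], test[mask]
    denom = np.linalg.norm(ref)
    if denom == 0:
        raise ValueError("reference image is identically zero")
    return float(np.linalg.norm(ref - test) / denom)


def density_weights(traj: Trajectory, interleaf: int = 0, floor: float = 1e-3) -> np.ndarray:
    """Analytic sample-density compensation for constant-pitch 2D spirals.

    The Voronoi cell of a sample on an interleaved constant-pitch spiral is
    (constant turn spacing) x (along-arm spacing), so the area per sample is
    proportional to the traversal speed |dk/dt| alone; a radius factor would
    apply to radial-fan geometries, not to spirals whose turns are uniformly
    spaced (checked against :func:`voronoi_weights` in the test suite).  For
    a constant-angular-rate spiral the speed grows like the radius, giving
    the familiar radius-proportional profile.  Weights are floored near the
    oversampled k-space origin and normalized to unit mean.
    """
    k = traj.k_samples[interleaf, :, :2]
    if np.allclose(k, 0):
        raise ValueError("degenerate (all-zero) trajectory")
    speed = np.linalg.norm(np.gradient(k, traj.times_s, axis=0), axis=1)
    w = np.maximum(speed, floor * speed.max())
    radius = np.linalg.norm(k, axis=1)
    angle = np.unwrap(np.arctan2(k[:, 1], k[:, 0]))
    total_turn = abs(angle[-1] - angle[0])
    if total_turn > 4 * np.pi:
        # inside the pitch radius the interleaf arms converge and the
        # transverse cell dimension shrinks like the radius
        pitch = (radius[-1] - radius[0]) / total_turn
        w = w * np.minimum(1.0, radius / pitch)
    w = np.maximum(w, floor * w.max())
    return w / w.mean()


def voronoi_weights(traj: Trajectory, interleaf: Optional[int] = None) -> np.ndarray:
    """Voronoi-cell-area density weights for arbitrary 2D trajectories.

    Cells are computed over the full interleaf set (density is set by all
    interleaves jointly); an unbounded cell on the k-space boundary inherits
    the area of the nearest bounded cell along its own readout.  Returns
    weights for one interleaf (or the first) normalized to unit mean.
    """
    from scipy.spatial import Voronoi

    pts = traj.k_samples[:, :, :2].reshape(-1, 2)
    # deduplicate coincident points (e.g. every interleaf starts at k=0)
    pts_unique, inverse = np.unique(np.round(pts, 9), axis=0, return_inverse=True)
    vor = Voronoi(pts_unique)
    areas = np.full(len(pts_unique), np.nan)
    for i, reg_idx in enumerate(vor.point_region):
        region = vor.regions[reg_idx]
        if -1 in region or len(region) == 0:
            continue
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * np.abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    if not np.isfinite(areas).any():
        raise ValueError("Voronoi weighting failed: no bounded cells")
    w_all = areas[inverse].reshape(traj.n_interleaves, traj.n_samples)
    # coincident samples share one cell: split its area evenly
    counts = np.bincount(inverse)
    w_all = w_all / counts[inverse].reshape(w_all.shape)
    for i in range(traj.n_interleaves):  # fill boundary cells along the readout
        row = w_all[i]
        bad = ~np.isfinite(row)
        if bad.any():
            good_idx = np.nonzero(~bad)[0]
            row[bad] = row[good_idx[np.searchsorted(good_idx, np.nonzero(bad)[0]).clip(max=good_idx.size - 1)]]
    w = w_all[interleaf if interleaf is not None else 0]
    return w / w.mean()


def conjugate_phase(
    op: EncodingOperator, data: KSpaceData, dcf: np.ndarray
) -> ReconResult:
    """Density-compensated adjoint reconstruction.

    ``dcf`` is a positive length-N_k weight vector applied to every interleaf
    and coil before the adjoint.
    """
    dcf = np.asarray(dcf, dtype=float)
    if dcf.shape != (data.n_samples,):
        raise ValueError("dcf must be a length-N_k vector")
    if np.any(dcf <= 0):
        raise ValueError("density weights must be positive")
    image = op.adjoint(data.samples * dcf[None, None, :])
    return ReconResult(image=image, method="conjugate_phase", L=op.L)


def conjugate_phase_rank_images(
    op: EncodingOperator, data: KSpaceData, dcf: np.ndarray
) -> np.ndarray:
    """Cumulative conjugate-phase images for every truncation rank.

    For a low-rank operator, the rank-L adjoint is a sum of L per-singular-
    vector contributions; accumulating them yields all L = 1..L_max
    conjugate-phase reconstructions for the price of one full-rank one.
    Returns an (L_max, N) array; row L-1 is the rank-L image.
    """
    if op.factors is None:
        raise ValueError("rank sweep requires a low-rank operator")
    dcf = np.asarray(dcf, dtype=float)
    weighted = data.samples * dcf[None, None, :]
    L_max = op.factors[0].L_max
    n = op.n_voxels
    contrib = np.zeros((L_max, n), dtype=complex)
    for i in range(op.n_interleaves):
        f = op.factors[i]
        y = weighted[i].T  # (N_k, N_c)
        for l in range(L_max):
            imgs = f.V[:, l : l + 1] * op.nuffts[i].adjoint(f.U[:, l : l + 1].conj() * y)
            contrib[l] += np.sum(op.coilmaps.maps.conj().T * imgs, axis=1)
    return np.cumsum(contrib, axis=0)


def solve_lsq(
    op: EncodingOperator,
    data: KSpaceData,
    max_iter: int = 15,
    tol: float = 1e-5,
    x0: Optional[np.ndarray] = None,
) -> ReconResult:
    """Iterative least-squares reconstruction (CGLS on the normal equations).

    Stops after ``max_iter`` iterations or when the normal-equation residual
    ||A^H (b - A x)|| has dropped below ``tol`` relative to its initial
    value.  The recorded residual history ||b - A x|| is non-increasing by
    construction of the Krylov iterates.
    """
    from ._solvers import cgls

    x, residuals, converged = cgls(
        op.forward, op.adjoint, data.samples, x0=x0, max_iter=max_iter, tol=tol
    )
    return ReconResult(x, "lsq", op.L, len(residuals) - 1, residuals, converged)
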