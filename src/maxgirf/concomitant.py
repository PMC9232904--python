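"""Concomitant (Maxwell) field model for a symmetric gradient system.

Whenever linear imaging gradients are active, Maxwell's equations force
transverse field components whose magnitude contribution is a sum of
spatial monomials weighted by quadratic (lowest order, ~1/B0) and cubic
(~1/B0^2) combinations of the gradient waveforms.  For a symmetric gradient
coil with transverse fields ``Bx = Gx z - Gz x / 2`` and ``By = Gy z -
Gz y / 2`` the expansion of ``|B|`` about ``B0 + G.r`` gives

lowest order (terms 4-9, basis in m^2, coefficients in T/m^2)::

    x^2 : Gz^2 / 8 B0          xy : 0
    y^2 : Gz^2 / 8 B0          yz : -Gy Gz / 2 B0
    z^2 : (Gx^2 + Gy^2)/ 2 B0  xz : -Gx Gz / 2 B0

cubic order (terms 10-19, basis in m^3, coefficients in T/m^3), obtained by
carrying the expansion one order further, ``-(Bx^2+By^2)(G.r)/(2 B0^2)``.

Everything here is a physical-frame quantity: the basis must be evaluated
at physical coordinates and the coefficients from physical-frame gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .geometry import PHYSICAL, FrameError, GradientSet, ScanGeometry, SpatialGrid

__all__ = [
    "BASIS_MONOMIALS",
    "ConcomitantModel",
    "HigherOrderPhase",
    "dynamic_coefficients",
    "phase_coefficients",
    "evaluate_basis",
    "compute_higher_order_phase",
    "time_averaged_field_map",
]

#: Monomial exponents (a, b, c) meaning x^a y^b z^c for terms 4..19.
BASIS_MONOMIALS = {
    4: (2, 0, 0),
    5: (0, 2, 0),
    6: (0, 0, 2),
    7: (1, 1, 0),
    8: (0, 1, 1),
    9: (1, 0, 1),
    10: (3, 0, 0),
    11: (0, 3, 0),
    12: (0, 0, 3),
    13: (2, 1, 0),
    14: (2, 0, 1),
    15: (1, 2, 0),
    16: (0, 2, 1),
    17: (1, 0, 2),
    18: (0, 1, 2),
    19: (1, 1, 1),
}

_LOWEST = tuple(range(4, 10))
_FULL = tuple(range(4, 20))


@dataclass(frozen=True)
class ConcomitantModel:
    """Which expansion terms to include, and the field strength they scale by."""

    B0: float
    order: str = "lowest"  # "lowest" (terms 4-9) or "full" (terms 4-19)

    def __post_init__(self):
        if self.order not in ("lowest", "full"):
            raise ValueError("order must be 'lowest' or 'full'")
        if not self.B0 > 0:
            raise ValueError("B0 must be positive")

    @property
    def terms(self) -> tuple:
        return _LOWEST if self.order == "lowest" else _FULL

    @property
    def n_terms(self) -> int:
        return len(self.terms)


def dynamic_coefficients(g: GradientSet, model: ConcomitantModel) -> np.ndarray:
    """Concomitant dynamic coefficients h_l(t), shape (N_i, N_k, N_l).

    Input gradients must be in the physical frame.  Units: T/m^2 for the
    quadratic terms, T/m^3 for the cubic terms.
    """
    if g.frame != PHYSICAL:
        raise FrameError("dynamic_coefficients requires physical-frame gradients")
    gx = g.samples[..., 0]
    gy = g.samples[..., 1]
    gz = g.samples[..., 2]
    b0 = model.B0
    cols = {
        4: gz**2 / (8 * b0),
        5: gz**2 / (8 * b0),
        6: (gx**2 + gy**2) / (2 * b0),
        7: np.zeros_like(gx),
        8: -gy * gz / (2 * b0),
        9: -gx * gz / (2 * b0),
    }
    if model.order == "full":
        b2 = 2 * b0 * b0
        cols.update(
            {
                10: -gx * gz**2 / (4 * b2),
                11: -gy * gz**2 / (4 * b2),
                12: -gz * (gx**2 + gy**2) / b2,
                13: -gy * gz**2 / (4 * b2),
                14: (gx**2 * gz - gz**3 / 4) / b2,
                15: -gx * gz**2 / (4 * b2),
                16: (gy**2 * gz - gz**3 / 4) / b2,
                17: -(gx * (gx**2 + gy**2) - gx * gz**2) / b2,
                18: -(gy * (gx**2 + gy**2) - gy * gz**2) / b2,
                19: 2 * gx * gy * gz / b2,
            }
        )
    return np.stack([cols[l] for l in model.terms], axis=-1)


def phase_coefficients(h: np.ndarray, times_s: np.ndarray, gamma: float) -> np.ndarray:
    """Phase coefficients k_l(t) = gamma * integral of h_l, trapezoid rule.

    ``h`` has shape (N_i, N_k, N_l); integration runs along the time axis and
    starts at zero at the first sample (the readout start, where the sequence
    is assumed to have nulled accumulated concomitant phase).
    """
    times_s = np.asarray(times_s, dtype=float)
    if np.any(np.diff(times_s) <= 0):
        raise ValueError("times_s must be strictly increasing")
    return gamma * cumulative_trapezoid(h, x=times_s, axis=-2, initial=0.0)


def evaluate_basis(grid_P: SpatialGrid, model: ConcomitantModel) -> np.ndarray:
    """Evaluate the monomial basis p_l(r) at physical-frame voxel positions.

    Returns shape (N, N_l) in m^2 / m^3 columns matching ``model.terms``.
    """
    if grid_P.frame != PHYSICAL:
        raise FrameError(
            "evaluate_basis requires a physical-frame grid: concomitant "
            "fields are defined in the gradient-coil frame"
        )
    x, y, z = grid_P.coords[:, 0], grid_P.coords[:, 1], grid_P.coords[:, 2]
    cols = []
    for l in model.terms:
        a, b, c = BASIS_MONOMIALS[l]
        cols.append(x**a * y**b * z**c)
    return np.stack(cols, axis=-1)


@dataclass
class HigherOrderPhase:
    """All pieces of the non-Fourier phase: phi~(r, t) for each interleaf.

    phi~_i(r_rho, t) = 2 pi df(r_rho) (t - t0) + sum_l k_l,i(t) p_l(r_rho)

    Fields
    ------
    k_coeffs : (N_i, N_k, N_l) phase coefficients, rad/m^2 or rad/m^3
    basis_values : (N, N_l) monomials at physical-frame voxel positions
    times_s : (N_k,) sample times relative to the phase reference
    deltaf_Hz : optional (N,) static off-resonance map
    """

    k_coeffs: np.ndarray
    basis_values: np.ndarray
    times_s: np.ndarray
    deltaf_Hz: Optional[np.ndarray] = None
    t0_s: float = 0.0

    @property
    def n_interleaves(self) -> int:
        return self.k_coeffs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.k_coeffs.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.basis_values.shape[0]

    def phase_matrix(self, interleaf: int, rows: Optional[slice] = None) -> np.ndarray:
        """Dense phi~ for one interleaf, shape (N_k, N), radians.

        ``rows`` selects a block of time samples for chunked evaluation.
        """
        rows = slice(None) if rows is None else rows
        phi = self.k_coeffs[interleaf, rows] @ self.basis_values.T
        if self.deltaf_Hz is not None:
            phi = phi + 2.0 * np.pi * np.outer(self.times_s[rows] - self.t0_s, self.deltaf_Hz)
        return phi


def compute_higher_order_phase(
    g_physical: GradientSet,
    grid_P: SpatialGrid,
    geom: ScanGeometry,
    model: ConcomitantModel,
    deltaf_Hz: Optional[np.ndarray] = None,
) -> HigherOrderPhase:
    """Convenience: coefficients + basis + off-resonance in one container."""
    h = dynamic_coefficients(g_physical, model)
    k = phase_coefficients(h, g_physical.times_s, geom.gamma)
    basis = evaluate_basis(grid_P, model)
    df = None if deltaf_Hz is None else np.asarray(deltaf_Hz, dtype=float).reshape(-1)
    if df is not None and df.size != grid_P.n_voxels:
        raise ValueError("deltaf_Hz length must equal the number of voxels")
    return HigherOrderPhase(
        k_coeffs=k,
        basis_values=basis,
        times_s=g_physical.times_s,
        deltaf_Hz=df,
        t0_s=g_physical.t0_s,
    )


def time_averaged_field_map(phase: HigherOrderPhase, T_s: float, interleaf: int = 0) -> np.ndarray:
    """Time-averaged concomitant field map in Hz over readout duration T.

    f_c(r) = (1 / 2 pi T) * sum_l k_l(T) p_l(r), using the terminal phase
    coefficients of the requested interleaf.  Off-resonance does not enter.
    """
    if not T_s > 0:
        raise ValueError("T_s must be positive")
    k_end = phase.k_coeffs[interleaf, -1, :]
    return (k_end @ phase.basis_values.T) / (2.0 * np.pi * T_s)
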