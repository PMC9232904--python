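"""Coordinate conventions, frames, k-space integration and slice-offset handling.

Two Cartesian frames are used throughout the package:

* the **logical** frame is aligned with the imaging slice (readout /
  phase-encode / slice axes); 2D slices live in the plane ``z_L = 0``;
* the **physical** frame is the gradient-coil (scanner) frame in which the
  concomitant (Maxwell) fields have their analytic form.

They are related by an orthogonal rotation ``r_P = R r_L + r_offset``.
Fourier encoding uses logical-frame trajectories and coordinates, while the
higher-order (concomitant) phase must be evaluated in the physical frame;
the frame tag carried by every container lets consumers enforce this.

All quantities are SI: gradients in T/m, positions in meters, k-space in
rad/m, time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "GAMMA_1H",
    "Frame",
    "ScanGeometry",
    "GradientSet",
    "Trajectory",
    "SpatialGrid",
    "axial_geometry",
    "sagittal_geometry",
    "coronal_geometry",
    "transform_to_physical",
    "transform_to_logical",
    "integrate_kspace",
    "demodulate_offset",
    "modulate_offset",
]

#: Proton gyromagnetic ratio in rad/s/T.
GAMMA_1H = 2.0 * np.pi * 42.5764e6

# Frame tags (kept as plain strings for h5py friendliness).
LOGICAL = "logical"
PHYSICAL = "physical"
Frame = str

_ORTHO_TOL = 1e-12


class FrameError(ValueError):
    """Raised when an operation receives data in the wrong coordinate frame."""


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > 1e-10:
        raise ValueError(f"rotation matrix is not orthogonal (|R^T R - I| = {err:.3g})")
    return R


@dataclass(frozen=True)
class ScanGeometry:
    """Slice prescription: logical-to-physical rotation, offset, field strength.

    Parameters
    ----------
    rotation_LtoP
        3x3 orthogonal matrix mapping logical vectors into the physical frame.
    offset_P
        Slice offset from isocenter, meters, physical frame.
    B0
        Main field strength in Tesla.
    gamma
        Gyromagnetic ratio in rad/s/T (proton by default).
    """

    rotation_LtoP: np.ndarray
    offset_P: np.ndarray = field(default_factory=lambda: np.zeros(3))
    B0: float = 0.55
    gamma: float = GAMMA_1H

    def __post_init__(self):
        object.__setattr__(self, "rotation_LtoP", _check_rotation(self.rotation_LtoP))
        offset = np.asarray(self.offset_P, dtype=float).reshape(3)
        object.__setattr__(self, "offset_P", offset)
        if not self.B0 > 0:
            raise ValueError("B0 must be positive")

    @property
    def rotation_PtoL(self) -> np.ndarray:
        return self.rotation_LtoP.T


def axial_geometry(z_offset_m: float = 0.0, B0: float = 0.55, gamma: float = GAMMA_1H) -> ScanGeometry:
    """Axial slice: logical axes coincide with physical axes, offset along z."""
    return ScanGeometry(np.eye(3), np.array([0.0, 0.0, z_offset_m]), B0, gamma)


def sagittal_geometry(x_offset_m: float = 0.0, B0: float = 0.55, gamma: float = GAMMA_1H) -> ScanGeometry:
    """Sagittal slice: logical (x, y, z) -> physical (y, z, x), offset along x."""
    R = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    return ScanGeometry(R, np.array([x_offset_m, 0.0, 0.0]), B0, gamma)


def oblique_sagittal_geometry(
    x_offset_m: float = 0.0,
    tilt_rad: float = 0.17,
    B0: float = 0.55,
    gamma: float = GAMMA_1H,
) -> ScanGeometry:
    """Sagittal slice tilted about the physical y-axis by ``tilt_rad``.

    A pure sagittal slice has constant physical x, which makes all
    x-dependent concomitant terms spatially flat over the slice; a slight
    obliquity (as in realistic scan prescriptions) re-activates them.
    """
    base = sagittal_geometry(0.0, B0, gamma)
    c, s = np.cos(tilt_rad), np.sin(tilt_rad)
    tilt = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return ScanGeometry(tilt @ base.rotation_LtoP, np.array([x_offset_m, 0.0, 0.0]), B0, gamma)


def coronal_geometry(y_offset_m: float = 0.0, B0: float = 0.55, gamma: float = GAMMA_1H) -> ScanGeometry:
    """Coronal slice: logical (x, y, z) -> physical (x, z, y), offset along y."""
    R = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return ScanGeometry(R, np.array([0.0, y_offset_m, 0.0]), B0, gamma)


@dataclass
class GradientSet:
    """Per-interleaf three-axis gradient waveforms.

    ``samples`` has shape (N_i, N_k, 3) in T/m on a uniform raster.
    ``t0_s`` is the time of the first readout sample relative to the phase
    reference (isodelay for gradient echo, TE for spin echo); phase-sensitive
    consumers measure time from that reference.
    """

    samples: np.ndarray
    raster_s: float
    frame: Frame = LOGICAL
    t0_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3 or self.samples.shape[-1] != 3:
            raise ValueError("gradient samples must have shape (N_i, N_k, 3)")
        if not self.raster_s > 0:
            raise ValueError("raster_s must be positive")
        if self.frame not in (LOGICAL, PHYSICAL):
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def n_interleaves(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        """Sample times relative to the phase reference."""
        return self.t0_s + np.arange(self.n_samples) * self.raster_s


@dataclass
class Trajectory:
    """Per-interleaf k-space trajectories, rad/m, shape (N_i, N_k, 3)."""

    k_samples: np.ndarray
    times_s: np.ndarray
    frame: Frame = LOGICAL

    def __post_init__(self):
        self.k_samples = np.asarray(self.k_samples, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.k_samples.ndim != 3 or self.k_samples.shape[-1] != 3:
            raise ValueError("k_samples must have shape (N_i, N_k, 3)")
        if self.times_s.shape != (self.k_samples.shape[1],):
            raise ValueError("times_s length must match N_k")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        if self.frame not in (LOGICAL, PHYSICAL):
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def n_interleaves(self) -> int:
        return self.k_samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.k_samples.shape[1]


@dataclass
class SpatialGrid:
    """Flattened 2D reconstruction grid.

    Voxel centers, origin at the matrix center, row-major flattening: the
    voxel (i1, i2) of an (N1, N2) matrix maps to flat index ``i1 * N2 + i2``.
    This is the single flattening convention used by every module.
    """

    shape: Tuple[int, int]
    fov_m: Tuple[float, float]
    coords: np.ndarray
    frame: Frame = LOGICAL
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = int(np.prod(self.shape))
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (N1*N2, 3)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool).reshape(n)
        if self.frame not in (LOGICAL, PHYSICAL):
            raise ValueError(f"unknown frame {self.frame!r}")

    @classmethod
    def make(cls, shape: Tuple[int, int], fov_m: Tuple[float, float]) -> "SpatialGrid":
        """Logical-frame grid of voxel centers with z_L = 0."""
        n1, n2 = shape
        f1, f2 = fov_m
        x = (np.arange(n1) - (n1 - 1) / 2.0) * (f1 / n1)
        y = (np.arange(n2) - (n2 - 1) / 2.0) * (f2 / n2)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        coords = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n1 * n2)])
        return cls(shape=(n1, n2), fov_m=(f1, f2), coords=coords, frame=LOGICAL)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


def _require_frame(obj, frame: Frame, what: str):
    if obj.frame != frame:
        raise FrameError(f"{what}: expected {frame}-frame input, got {obj.frame}")


def transform_to_physical(obj, geom: ScanGeometry):
    """Rotate a logical-frame object into the physical frame.

    Vector quantities (gradients, trajectories) rotate; spatial grids rotate
    and are additionally translated by the slice offset.
    """
    R = geom.rotation_LtoP
    _require_frame(obj, LOGICAL, "transform_to_physical")
    if isinstance(obj, GradientSet):
        return replace(obj, samples=obj.samples @ R.T, frame=PHYSICAL)
    if isinstance(obj, Trajectory):
        return replace(obj, k_samples=obj.k_samples @ R.T, frame=PHYSICAL)
    if isinstance(obj, SpatialGrid):
        return replace(obj, coords=obj.coords @ R.T + geom.offset_P, frame=PHYSICAL)
    raise TypeError(f"unsupported type {type(obj).__name__}")


def transform_to_logical(obj, geom: ScanGeometry):
    """Inverse of :func:`transform_to_physical` (R_PtoL = R^T)."""
    R = geom.rotation_PtoL
    _require_frame(obj, PHYSICAL, "transform_to_logical")
    if isinstance(obj, GradientSet):
        return replace(obj, samples=obj.samples @ R.T, frame=LOGICAL)
    if isinstance(obj, Trajectory):
        return replace(obj, k_samples=obj.k_samples @ R.T, frame=LOGICAL)
    if isinstance(obj, SpatialGrid):
        return replace(obj, coords=(obj.coords - geom.offset_P) @ R.T, frame=LOGICAL)
    raise TypeError(f"unsupported type {type(obj).__name__}")


def integrate_kspace(g: GradientSet, geom: ScanGeometry) -> Trajectory:
    """k(t) = gamma * cumulative integral of G from the start of the readout.

    Cumulative trapezoid on the gradient raster; k is zero at the first
    sample (the sequence is assumed to null all encoding phase at the phase
    reference, and the readout starts there).
    """
    k = geom.gamma * cumulative_trapezoid(
        g.samples, dx=g.raster_s, axis=1, initial=0.0
    )
    return Trajectory(k_samples=k, times_s=g.times_s, frame=g.frame)


def demodulate_offset(samples: np.ndarray, traj_P: Trajectory, geom: ScanGeometry) -> np.ndarray:
    """Remove the slice-offset phase modulation from raw k-space samples.

    Off-isocenter acquisitions are modulated by ``exp(-j k_P(t) . r_offset)``;
    this multiplies each sample by the conjugate phasor so that subsequent
    concomitant-field correction sees voxels at their true locations.

    ``samples`` has shape (N_i, N_c, N_k) (or (N_i, N_k)); the trajectory must
    be in the physical frame.
    """
    _require_frame(traj_P, PHYSICAL, "demodulate_offset")
    samples = np.asarray(samples)
    if samples.shape[-1] != traj_P.n_samples or samples.shape[0] != traj_P.n_interleaves:
        raise ValueError("sample/trajectory dimension mismatch")
    phase = traj_P.k_samples @ geom.offset_P  # (N_i, N_k)
    phasor = np.exp(1j * phase)
    if samples.ndim == 3:
        phasor = phasor[:, None, :]
    return samples * phasor


def modulate_offset(samples: np.ndarray, traj_P: Trajectory, geom: ScanGeometry) -> np.ndarray:
    """Inverse of :func:`demodulate_offset` (applies exp(-j k_P . r_offset))."""
    _require_frame(traj_P, PHYSICAL, "modulate_offset")
    samples = np.asarray(samples)
    if samples.shape[-1] != traj_P.n_samples or samples.shape[0] != traj_P.n_interleaves:
        raise ValueError("sample/trajectory dimension mismatch")
    phase = traj_P.k_samples @ geom.offset_P
    phasor = np.exp(-1j * phase)
    if samples.ndim == 3:
        phasor = phasor[:, None, :]
    return samples * phasor
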