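"""Synthetic acquisition generation: phantom, coils, off-resonance, k-space.

Everything the reconstruction pipeline consumes can be generated here with
no scanner data: an ellipse-sum digital phantom, smooth complex coil
sensitivity maps, a smooth (optionally fat-shifted) off-resonance map, and
multi-coil spiral k-space synthesized through the exact dense encoding
operator with complex Gaussian noise.  Field strength and off-isocenter
dependence of the concomitant fields enter through the scan geometry and
the concomitant model, so B0 / offset sweeps need only vary those.

Relaxation during the readout is deliberately not simulated (the encoding
model has no decay term; the magnetization is static over a readout).  To
avoid committing an inverse crime, synthesis may run on a finer grid than
reconstruction (``sim_oversample=2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Tuple

import numpy as np

from .concomitant import ConcomitantModel, compute_higher_order_phase
from .encoding import CoilMaps, KSpaceData
from .geometry import (
    GradientSet,
    ScanGeometry,
    SpatialGrid,
    Trajectory,
    integrate_kspace,
    modulate_offset,
    transform_to_physical,
)

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "NoiseModel",
    "make_phantom",
    "make_coilmaps",
    "make_offresonance",
    "simulate_acquisition",
    "default_phantom_spec",
]


@dataclass(frozen=True)
class Ellipse:
    """center (m), semi-axes (m), rotation angle (rad), complex amplitude."""

    center: Tuple[float, float]
    axes: Tuple[float, float]
    angle: float = 0.0
    amplitude: complex = 1.0


@dataclass
class PhantomSpec:
    ellipses: List[Ellipse] = dc_field(default_factory=list)

    def __post_init__(self):
        for e in self.ellipses:
            if not np.isfinite(e.amplitude):
                raise ValueError("ellipse amplitudes must be finite")


def default_phantom_spec(fov_m: float = 0.24) -> PhantomSpec:
    """A head-like ellipse phantom scaled to the field of view."""
    s = fov_m / 0.24
    return PhantomSpec(
        ellipses=[
            Ellipse((0.0, 0.0), (0.092 * s, 0.069 * s), 0.0, 1.0),
            Ellipse((0.0, 0.0), (0.0874 * s, 0.0644 * s), 0.0, -0.2),
            Ellipse((0.022 * s, 0.0), (0.031 * s, 0.011 * s), -np.pi / 10, -0.3),
            Ellipse((-0.022 * s, 0.0), (0.041 * s, 0.016 * s), np.pi / 10, -0.3),
            Ellipse((0.0, 0.035 * s), (0.025 * s, 0.021 * s), 0.0, 0.35),
            Ellipse((0.0, -0.01 * s), (0.0046 * s, 0.0046 * s), 0.0, 0.35),
            Ellipse((-0.008 * s, -0.0605 * s), (0.0046 * s, 0.023 * s), 0.0, 0.3),
            Ellipse((0.06 * s, -0.0105 * s), (0.0056 * s, 0.04 * s), np.pi / 2, 0.4),
        ]
    )


def make_phantom(spec: PhantomSpec, grid: SpatialGrid) -> np.ndarray:
    """Rasterize the ellipse sum at voxel centers; returns a flat (N,) image."""
    img = np.zeros(grid.n_voxels, dtype=complex)
    x = grid.coords[:, 0]
    y = grid.coords[:, 1]
    for e in spec.ellipses:
        ct, st = np.cos(e.angle), np.sin(e.angle)
        xr = (x - e.center[0]) * ct + (y - e.center[1]) * st
        yr = -(x - e.center[0]) * st + (y - e.center[1]) * ct
        inside = (xr / e.axes[0]) ** 2 + (yr / e.axes[1]) ** 2 <= 1.0
        img[inside] += e.amplitude
    return img


def make_coilmaps(n_coils: int, grid: SpatialGrid, phase_ramp: float = 1.5) -> CoilMaps:
    """Smooth complex sensitivities: Gaussian lobes on the FOV perimeter.

    Each coil is a broad Gaussian centered just outside the field of view at
    angle 2 pi c / n_coils, with a gentle linear phase toward its center.
    The maps are band-limited and their sum of squares is positive at every
    voxel.  ``n_coils = 1`` returns a uniform map.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if n_coils == 1:
        return CoilMaps.uniform(grid.n_voxels)
    fov = float(np.mean(grid.fov_m))
    radius = 0.55 * fov
    width = 0.6 * fov
    x, y = grid.coords[:, 0], grid.coords[:, 1]
    maps = np.empty((n_coils, grid.n_voxels), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        cx, cy = radius * np.cos(ang), radius * np.sin(ang)
        mag = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2)))
        phase = phase_ramp * (x * np.cos(ang) + y * np.sin(ang)) / fov
        maps[c] = mag * np.exp(1j * phase)
    return CoilMaps(maps)


def make_offresonance(
    grid: SpatialGrid,
    peak_Hz: float,
    fat_region: Optional[Ellipse] = None,
    fat_shift_Hz: float = -88.0,
) -> np.ndarray:
    """Smooth off-resonance map, optionally with a sharp fat-shifted region.

    The smooth background is a broad Gaussian bump plus a linear ramp,
    rescaled so its maximum magnitude equals ``peak_Hz``.  If ``fat_region``
    is given, ``fat_shift_Hz`` (chemical shift; -88 Hz corresponds to
    -3.8 ppm at 0.55 T) is added inside that ellipse with a sharp boundary.
    """
    x, y = grid.coords[:, 0], grid.coords[:, 1]
    fov = float(np.mean(grid.fov_m))
    bump = np.exp(-((x - 0.1 * fov) ** 2 + (y + 0.05 * fov) ** 2) / (2 * (0.35 * fov) ** 2))
    ramp = 0.3 * (x / fov)
    base = bump + ramp
    m = np.abs(base).max()
    df = np.zeros(grid.n_voxels) if m == 0 or peak_Hz == 0 else peak_Hz * base / m
    if fat_region is not None:
        ct, st = np.cos(fat_region.angle), np.sin(fat_region.angle)
        xr = (x - fat_region.center[0]) * ct + (y - fat_region.center[1]) * st
        yr = -(x - fat_region.center[0]) * st + (y - fat_region.center[1]) * ct
        inside = (xr / fat_region.axes[0]) ** 2 + (yr / fat_region.axes[1]) ** 2 <= 1.0
        df = df + np.where(inside, fat_shift_Hz, 0.0)
    return df


def _chunked_forward(traj_L, grid, phase, coilmaps, m, block: int = 256) -> np.ndarray:
    """Evaluate d_ic = (F o H)(S_c m) in time-row blocks.

    One complex exponential per matrix entry and no cached (N_k, N) matrix,
    so fine synthesis grids stay cheap in memory.
    """
    n_i, n_k = traj_L.n_interleaves, traj_L.n_samples
    weighted = coilmaps.maps.T * m[:, None]  # (N, N_c)
    out = np.empty((n_i, coilmaps.n_coils, n_k), dtype=complex)
    coords = grid.coords
    for i in range(n_i):
        k = traj_L.k_samples[i]
        for start in range(0, n_k, block):
            rows = slice(start, min(start + block, n_k))
            ph = k[rows] @ coords.T
            if phase is not None:
                ph = ph + phase.phase_matrix(i, rows)
            out[i, :, rows] = (np.exp(-1j * ph) @ weighted).T
    return out


@dataclass(frozen=True)
class NoiseModel:
    """i.i.d. complex Gaussian noise per sample and coil."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def simulate_acquisition(
    phantom: np.ndarray,
    coilmaps: CoilMaps,
    deltaf_Hz: Optional[np.ndarray],
    grid: SpatialGrid,
    geom: ScanGeometry,
    gradients: GradientSet,
    model: Optional[ConcomitantModel] = None,
    noise: NoiseModel = NoiseModel(),
    apply_offset_modulation: bool = True,
) -> KSpaceData:
    """Synthesize multi-coil k-space through the dense encoding operator.

    ``gradients`` are logical-frame waveforms; the physical-frame transform,
    k-space integration and concomitant phase evaluation all happen here so
    B0 and off-isocenter dependence follow from ``geom`` and ``model``.  If
    ``apply_offset_modulation`` the emitted data carry the raw slice-offset
    phase modulation (as acquired off-isocenter); the reconstruction side
    must then demodulate first.
    """
    if grid.frame != "logical":
        raise ValueError("simulate_acquisition expects a logical-frame grid")
    g_phys = transform_to_physical(gradients, geom)
    traj_L = integrate_kspace(gradients, geom)
    traj_P = integrate_kspace(g_phys, geom)
    grid_P = transform_to_physical(grid, geom)

    phase = None
    if model is not None or deltaf_Hz is not None:
        phase = compute_higher_order_phase(
            g_phys,
            grid_P,
            geom,
            model if model is not None else ConcomitantModel(B0=geom.B0),
            deltaf_Hz=deltaf_Hz,
        )
        if model is None:
            phase.k_coeffs = np.zeros_like(phase.k_coeffs)
    samples = _chunked_forward(
        traj_L, grid, phase, coilmaps, np.asarray(phantom, dtype=complex).ravel()
    )
    if apply_offset_modulation:
        samples = modulate_offset(samples, traj_P, geom)
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        samples = samples + noise.sigma * (
            rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        )
    return KSpaceData(samples=samples, dwell_s=gradients.raster_s, noise_sigma=noise.sigma or None)
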