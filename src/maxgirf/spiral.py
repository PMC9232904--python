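"""Slew- and amplitude-constrained Archimedean spiral gradient design.

The generator produces constant-density spiral readouts used as fixtures for
the encoding/reconstruction pipeline: one base interleaf ``k(theta) =
a * theta * exp(j theta)`` traversed as fast as the gradient amplitude and
slew-rate limits allow (slew-limited near the k-space origin, amplitude-
limited outside), plus rotated copies spanning 2 pi.  The pitch ``a =
n_interleaves / fov`` places adjacent turns of the full interleaf set at the
Nyquist spacing ``2 pi / fov`` rad/m.
"""

from __future__ import annotations

import numpy as np

from .geometry import GAMMA_1H, LOGICAL, GradientSet

__all__ = ["design_spiral"]


class SpiralDesignError(RuntimeError):
    """Raised when the requested resolution is unreachable under constraints."""


def _integrate_theta(
    a: float,
    theta_end: float,
    gmax: float,
    smax: float,
    gamma: float,
    dt: float,
    max_steps: int,
    safety: float,
):
    """March theta(t) forward with capped angular velocity/acceleration.

    The amplitude cap is |G| = (a/gamma) sqrt(1+theta^2) theta_dot <= gmax.
    The slew budget is split between the curvature term sqrt(4+theta^2)
    theta_dot^2 and the acceleration term sqrt(1+theta^2) theta_ddot, which
    bounds |dG/dt| conservatively.
    """
    g_budget = gamma * gmax * safety / a
    s_budget = gamma * smax * safety / a
    theta = 0.0
    v = 0.0
    thetas = [0.0]
    for _ in range(max_steps):
        curv = np.sqrt(4.0 + theta**2)
        v_amp = g_budget / np.sqrt(1.0 + theta**2)
        v_slew = np.sqrt(s_budget / curv)  # curvature term alone saturates slew
        v_tgt = min(v_amp, v_slew)
        if v < v_tgt:
            acc_room = max(s_budget - curv * v * v, 0.0) / np.sqrt(1.0 + theta**2)
            v = min(v + acc_room * dt, v_tgt)
        else:
            v = v_tgt
        theta += v * dt
        thetas.append(theta)
        if theta >= theta_end:
            return np.asarray(thetas)
    raise SpiralDesignError(
        "spiral design infeasible: k-space edge not reached within the "
        "maximum readout duration; relax resolution or raise gmax/smax"
    )


def design_spiral(
    fov_m: float,
    resolution_m: float,
    n_interleaves: int,
    gmax_T_per_m: float = 24e-3,
    smax_T_per_m_s: float = 144.0,
    dwell_s: float = 2.5e-6,
    gamma: float = GAMMA_1H,
    max_duration_s: float = 0.05,
    safety: float = 0.92,
) -> GradientSet:
    """Design a uniform-density spiral gradient set in the logical frame.

    Returns a :class:`GradientSet` whose interleaves are rotated copies of a
    single base waveform, satisfying |G| <= gmax and |dG/dt| <= smax at every
    sample, and reaching terminal k-radius >= pi / resolution.

    Raises
    ------
    SpiralDesignError
        If the k-space edge cannot be reached within ``max_duration_s``.
    """
    if min(fov_m, resolution_m, gmax_T_per_m, smax_T_per_m_s, dwell_s) <= 0:
        raise ValueError("all spiral design parameters must be positive")
    if n_interleaves < 1:
        raise ValueError("n_interleaves must be >= 1")

    a = n_interleaves / fov_m  # rad/m of k-radius per rad of spiral angle
    k_max = np.pi / resolution_m
    theta_end = 1.005 * k_max / a  # small overshoot absorbs integration error

    fine = 8  # internal sub-raster per dwell
    dt = dwell_s / fine
    max_steps = int(np.ceil(max_duration_s / dt))
    thetas = _integrate_theta(
        a, theta_end, gmax_T_per_m, smax_T_per_m_s, gamma, dt, max_steps, safety
    )

    # analytic gradient G = (a/gamma)(1 + j theta) e^{j theta} theta_dot on
    # the fine raster, then decimated to the ADC dwell grid
    v = np.gradient(thetas, dt)
    v[0] = 0.0  # the gradient waveform starts from rest
    g_fine = (a / gamma) * (1.0 + 1j * thetas) * np.exp(1j * thetas) * v
    n_k = len(thetas[::fine])
    g_base = g_fine[::fine][:n_k]

    rot = np.exp(2j * np.pi * np.arange(n_interleaves) / n_interleaves)
    g_all = g_base[None, :] * rot[:, None]  # (N_i, N_k) complex
    samples = np.zeros((n_interleaves, n_k, 3))
    samples[:, :, 0] = g_all.real
    samples[:, :, 1] = g_all.imag
    return GradientSet(samples=samples, raster_s=dwell_s, frame=LOGICAL, t0_s=0.0)
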