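"""Gradient impulse response functions: an LTI model of the gradient chain.

The gradient system (amplifier, coil, eddy currents, mechanical resonances)
is modelled per physical axis as a linear time-invariant system with a
complex transfer function ``T_a(f)``.  Predicted gradients are obtained by
filtering the nominal physical-frame waveforms through the measured (or, for
testing, synthesized) transfer function.  Only self-terms are applied; B0
cross-terms may be stored but do not enter the prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .geometry import PHYSICAL, GradientSet

__all__ = ["GirfModel", "predict_gradients", "synthesize_girf"]

_AXES = ("x", "y", "z")


@dataclass
class GirfModel:
    """Per-axis complex transfer functions on a common frequency grid.

    ``freq_Hz`` is an ascending grid covering negative and positive
    frequencies; ``transfer`` has shape (3, M) ordered (x, y, z).  A real
    impulse response requires Hermitian symmetry ``T(-f) = conj(T(f))``,
    checked at construction on (approximately) mirrored grid points.
    """

    freq_Hz: np.ndarray
    transfer: np.ndarray
    b0_cross: Optional[np.ndarray] = None

    def __post_init__(self):
        self.freq_Hz = np.asarray(self.freq_Hz, dtype=float)
        self.transfer = np.asarray(self.transfer, dtype=complex)
        if self.transfer.shape != (3, self.freq_Hz.size):
            raise ValueError("transfer must have shape (3, len(freq_Hz))")
        if np.any(np.diff(self.freq_Hz) <= 0):
            raise ValueError("freq_Hz must be strictly increasing")
        self._check_hermitian()
        t0 = self.dc_gain
        if np.any(t0 <= 0) or np.any(t0 > 1.2):
            raise ValueError("|transfer(0)| must lie in (0, 1.2]")

    def _check_hermitian(self, tol: float = 1e-9):
        f = self.freq_Hz
        # compare T(f) against conj(T(-f)) where the mirrored point exists
        idx = np.searchsorted(f, -f)
        valid = (idx < f.size) & np.isclose(f[np.minimum(idx, f.size - 1)], -f, atol=1e-9)
        if valid.sum() < 2:
            return
        j = idx[valid]
        err = np.abs(self.transfer[:, valid] - np.conj(self.transfer[:, j])).max()
        if err > 1e-6:
            raise ValueError(
                f"transfer is not Hermitian-symmetric (max asymmetry {err:.3g}); "
                "a real impulse response requires T(-f) = conj(T(f))"
            )

    @property
    def dc_gain(self) -> np.ndarray:
        return np.abs(
            np.array([np.interp(0.0, self.freq_Hz, self.transfer[a].real) for a in range(3)])
            + 1j * np.array([np.interp(0.0, self.freq_Hz, self.transfer[a].imag) for a in range(3)])
        )

    def fitted_delay_s(self) -> np.ndarray:
        """Per-axis group delay from a least-squares linear fit to the phase."""
        out = np.zeros(3)
        f = self.freq_Hz
        w = np.abs(self.transfer)
        for a in range(3):
            phase = np.unwrap(np.angle(self.transfer[a]))
            denom = np.sum(w[a] * f * f)
            out[a] = 0.0 if denom == 0 else -np.sum(w[a] * f * phase) / (2 * np.pi * denom)
        return out

    def sample(self, freq_Hz: np.ndarray) -> np.ndarray:
        """Resample the transfer functions onto an arbitrary frequency grid.

        Inside the measured band magnitude and unwrapped phase are
        interpolated linearly (exact for pure delays, whose phase is linear
        in frequency).  Outside the band the edge magnitude is held and the
        phase is extrapolated linearly using the fitted delay (the
        out-of-band behaviour is a package decision; measured GIRFs rarely
        cover the full waveform bandwidth).
        """
        freq_Hz = np.asarray(freq_Hz, dtype=float)
        out = np.empty((3, freq_Hz.size), dtype=complex)
        f_lo, f_hi = self.freq_Hz[0], self.freq_Hz[-1]
        delays = self.fitted_delay_s()
        oob = (freq_Hz < f_lo) | (freq_Hz > f_hi)
        for a in range(3):
            mag = np.interp(freq_Hz, self.freq_Hz, np.abs(self.transfer[a]))
            phase = np.interp(
                freq_Hz, self.freq_Hz, np.unwrap(np.angle(self.transfer[a]))
            )
            out[a] = mag * np.exp(1j * phase)
            if np.any(oob):
                edge_mag = np.where(
                    freq_Hz[oob] < f_lo, np.abs(self.transfer[a, 0]), np.abs(self.transfer[a, -1])
                )
                out[a, oob] = edge_mag * np.exp(-2j * np.pi * freq_Hz[oob] * delays[a])
        return out


def _pad_length(n: int) -> int:
    """Next power of two >= 4n, so circular convolution ~ linear convolution."""
    return 1 << int(np.ceil(np.log2(4 * n)))


def predict_gradients(g_nom: GradientSet, girf: GirfModel, pad_factor: int = 4) -> GradientSet:
    """Filter nominal physical-frame gradients through per-axis GIRFs.

    The waveform on each physical axis is zero-padded (to at least
    ``pad_factor`` times its length, rounded up to a power of two),
    transformed, multiplied by the axis transfer function resampled onto the
    waveform's frequency grid, and transformed back.  The output is real and
    keeps the input raster and length.
    """
    if g_nom.frame != PHYSICAL:
        raise ValueError(
            "predict_gradients requires physical-frame gradients: GIRFs act "
            "per physical axis (transform first, then predict)"
        )
    n_k = g_nom.n_samples
    n_pad = 1 << int(np.ceil(np.log2(max(2, pad_factor * n_k))))
    freqs = np.fft.rfftfreq(n_pad, d=g_nom.raster_s)
    band = 0.5 / g_nom.raster_s
    if girf.freq_Hz[-1] < band:
        warnings.warn(
            "GIRF bandwidth is below the waveform bandwidth; the transfer "
            "function is extrapolated outside the measured band",
            stacklevel=2,
        )
    transfer = girf.sample(freqs)  # (3, n_pad//2+1)
    out = np.empty_like(g_nom.samples)
    for axis in range(3):
        spec = np.fft.rfft(g_nom.samples[:, :, axis], n=n_pad, axis=1)
        filtered = np.fft.irfft(spec * transfer[axis][None, :], n=n_pad, axis=1)
        out[:, :, axis] = filtered[:, :n_k]
    return replace(g_nom, samples=out)


def synthesize_girf(
    delay_s: float = 1e-6,
    cutoff_Hz: float = 30e3,
    osc_freq_Hz: float = 0.0,
    osc_amp: float = 0.0,
    freq_grid: Optional[np.ndarray] = None,
    osc_q: float = 10.0,
) -> GirfModel:
    """Synthesize a plausible GIRF: lowpass x delay x mechanical resonance.

    ``transfer(f) = exp(-(f/cutoff)^2) * exp(-2j pi f delay) *
    (1 + osc_amp * (j f / f0) / (1 - (f/f0)^2 + j f/(Q f0)))``

    The construction is Hermitian-symmetric by inspection, so the impulse
    response is real.  ``cutoff_Hz = np.inf`` disables the lowpass.
    """
    if not cutoff_Hz > 0:
        raise ValueError("cutoff_Hz must be positive")
    if freq_grid is None:
        freq_grid = np.linspace(-200e3, 200e3, 4001)
    f = np.asarray(freq_grid, dtype=float)
    if np.isfinite(cutoff_Hz):
        lowpass = np.exp(-((f / cutoff_Hz) ** 2))
    else:
        lowpass = np.ones_like(f)
    transfer = lowpass * np.exp(-2j * np.pi * f * delay_s)
    if osc_amp != 0.0 and osc_freq_Hz > 0.0:
        x = f / osc_freq_Hz
        transfer = transfer * (1.0 + osc_amp * (1j * x) / (1.0 - x * x + 1j * x / osc_q))
    return GirfModel(freq_Hz=f, transfer=np.tile(transfer, (3, 1)))
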