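"""Static off-resonance (B0) mapping from multi-echo gradient-echo images.

The per-voxel signal of the m-th echo is modelled as

    F_m(rho, df) = rho * exp(j 2 pi df TE_m),

with complex content ``rho`` (water + fat; the model deliberately folds the
chemical shift into the field map, e.g. -88 Hz at 0.55 T) and off-resonance
``df`` in Hz.  The joint estimate is obtained by an iteratively regularized
Gauss-Newton (IRGN) scheme on preconditioned variables ``x = W x^``, where W
is the identity on the content channel and a Sobolev spectral weight
``(1 + w ||k||^2)^(-h)`` on the field-map channel (k normalized to
[-0.5, 0.5]^2), which confines the field map to smooth spatial variations.
Each linearized subproblem

    min_d ||J d - r||^2 + alpha_n ||x^_n + d - x^_0||^2

is solved with the shared conjugate-direction least-squares solver; the
regularization alpha_n = max(2^-n, alpha_min) halves per outer iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ._solvers import cgls

__all__ = [
    "MultiEchoData",
    "FieldMapEstimate",
    "forward_echo_model",
    "apply_sobolev",
    "sobolev_weights",
    "estimate_fieldmap",
]


@dataclass
class MultiEchoData:
    """Coil-combined echo images: ``echoes`` (N_e, N) at TEs ``te_s``."""

    echoes: np.ndarray
    te_s: np.ndarray
    shape: Tuple[int, int]

    def __post_init__(self):
        self.echoes = np.asarray(self.echoes, dtype=complex)
        self.te_s = np.asarray(self.te_s, dtype=float)
        if self.echoes.ndim != 2 or self.echoes.shape[0] != self.te_s.size:
            raise ValueError("echoes must have shape (N_e, N) matching te_s")
        if self.te_s.size < 2:
            raise ValueError("at least two echoes are required")
        if np.any(np.diff(self.te_s) <= 0):
            raise ValueError("TEs must be strictly increasing")
        if int(np.prod(self.shape)) != self.echoes.shape[1]:
            raise ValueError("shape does not match the voxel count")


@dataclass
class FieldMapEstimate:
    """Estimated content and field map plus estimation provenance."""

    rho: np.ndarray
    deltaf_Hz: np.ndarray
    w: float
    h: float
    alpha_history: List[float] = field(default_factory=list)
    objective_history: List[float] = field(default_factory=list)

    def support_mask(self, rel_threshold: float = 0.1) -> np.ndarray:
        return np.abs(self.rho) > rel_threshold * np.abs(self.rho).max()


def forward_echo_model(rho: np.ndarray, deltaf_Hz: np.ndarray, te_s: np.ndarray) -> np.ndarray:
    """Evaluate the echo stack, shape (N_e, N): rho * exp(j 2 pi df TE_m)."""
    rho = np.asarray(rho)
    te_s = np.asarray(te_s, dtype=float)
    return rho[None, :] * np.exp(2j * np.pi * np.outer(te_s, deltaf_Hz))


def sobolev_weights(shape: Tuple[int, int], w: float, h: float) -> np.ndarray:
    """Spectral weight (1 + w ||k||^2)^(-h) on the fftfreq grid of ``shape``."""
    kx = np.fft.fftfreq(shape[0])
    ky = np.fft.fftfreq(shape[1])
    k2 = kx[:, None] ** 2 + ky[None, :] ** 2
    return (1.0 + w * k2) ** (-h)


def apply_sobolev(
    vec: np.ndarray, shape: Tuple[int, int], w: float, h: float, direction: str = "forward"
) -> np.ndarray:
    """Apply the Sobolev smoothing operator P = F^-1 diag(weight) F.

    ``direction='forward'`` multiplies by the weight in k-space (smooths);
    ``'inverse'`` divides (exactly undoes the forward map).  The transform is
    unitary so P is self-adjoint; the weight is 1 at k = 0 (DC preserved).
    """
    weight = sobolev_weights(shape, w, h)
    if direction == "inverse":
        weight = 1.0 / weight
    elif direction != "forward":
        raise ValueError("direction must be 'forward' or 'inverse'")
    v2 = np.asarray(vec).reshape(shape)
    out = np.fft.ifft2(np.fft.fft2(v2, norm="ortho") * weight, norm="ortho")
    return out.reshape(np.asarray(vec).shape)


def estimate_fieldmap(
    data: MultiEchoData,
    w: float = 32.0,
    h: float = 16.0,
    alpha_min: float = 1e-6,
    gn_iters: int = 35,
    inner_iters: int = 250,
    inner_tol: float = 1e-10,
    data_scale: float = 100.0,
) -> FieldMapEstimate:
    """IRGN estimation of (rho, deltaf) from multi-echo images.

    Defaults follow the intended operating point of the method: Sobolev
    constants w = 32, h = 16, regularization floor 1e-6, 35 Gauss-Newton
    iterations with up to 250 inner least-squares iterations at tolerance
    1e-10.  Echo data are normalized internally so that the peak magnitude is
    ``data_scale`` (the absolute regularization level is meaningful only
    relative to the data scale); the returned ``rho`` is un-normalized.

    The initial guess is rho = first echo, deltaf = 0.  If the data residual
    increases over three consecutive outer iterations the iteration stops
    and the best iterate is returned.
    """
    n_e, n = data.echoes.shape
    shape = data.shape
    te = data.te_s
    peak = np.abs(data.echoes).max()
    if peak == 0:
        return FieldMapEstimate(np.zeros(n, complex), np.zeros(n), w, h)
    scale = data_scale / peak
    y = data.echoes * scale

    weight = sobolev_weights(shape, w, h)

    def smooth(v: np.ndarray) -> np.ndarray:
        return np.fft.ifft2(
            np.fft.fft2(v.reshape(shape), norm="ortho") * weight, norm="ortho"
        ).ravel()

    # unknowns in preconditioned space: xh = (rho_hat, dfh); df = P dfh
    rho_hat0 = y[0].copy()
    dfh0 = np.zeros(n, dtype=complex)
    x0 = np.concatenate([rho_hat0, dfh0])
    x = x0.copy()

    def model_and_jacobian(xh: np.ndarray):
        rho = xh[:n]
        df = smooth(xh[n:])
        e = np.exp(2j * np.pi * np.outer(te, df))  # (N_e, N)
        g = rho[None, :] * e
        jac_df = 2j * np.pi * te[:, None] * g  # dF/d(df), per echo

        def jfwd(d: np.ndarray) -> np.ndarray:
            d_rho, d_dfh = d[:n], d[n:]
            d_df = smooth(d_dfh)
            return (e * d_rho[None, :] + jac_df * d_df[None, :]).ravel()

        def jadj(r: np.ndarray) -> np.ndarray:
            r = r.reshape(n_e, n)
            g_rho = np.sum(np.conj(e) * r, axis=0)
            g_dfh = smooth(np.sum(np.conj(jac_df) * r, axis=0))
            return np.concatenate([g_rho, g_dfh])

        return g, jfwd, jadj

    alpha_history: List[float] = []
    obj_history: List[float] = []
    best_x = x.copy()
    best_res = np.inf
    n_increase = 0
    for it in range(gn_iters):
        alpha = max(2.0 ** (-it), alpha_min)
        alpha_history.append(alpha)
        g, jfwd, jadj = model_and_jacobian(x)
        r = (y - g).ravel()
        res = float(np.linalg.norm(r))
        obj_history.append(res)
        if res < best_res:
            best_res = res
            best_x = x.copy()
            n_increase = 0
        else:
            n_increase += 1
            if n_increase >= 3:
                break
        sq = np.sqrt(alpha)

        def afwd(d: np.ndarray) -> np.ndarray:
            return np.concatenate([jfwd(d), sq * d])

        def aadj(rr: np.ndarray) -> np.ndarray:
            return jadj(rr[: n_e * n]) + sq * rr[n_e * n :]

        rhs = np.concatenate([r, sq * (x0 - x)])
        delta, _, _ = cgls(afwd, aadj, rhs, max_iter=inner_iters, tol=inner_tol)
        x = x + delta

    # final bookkeeping on the best iterate
    g, _, _ = model_and_jacobian(x)
    if float(np.linalg.norm((y - g).ravel())) > best_res:
        x = best_x
    rho = x[:n] / scale
    df = smooth(x[n:])
    return FieldMapEstimate(
        rho=rho,
        deltaf_Hz=df.real,
        w=w,
        h=h,
        alpha_history=alpha_history,
        objective_history=obj_history,
    )
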