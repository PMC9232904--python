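"""Low-rank factorization of higher-order encoding matrices.

The higher-order phase matrix H (N_k x N, unit-modulus entries) is strongly
compressible: its singular values decay quickly because both the temporal
phase coefficients and the spatial maps are smooth.  A rank-L truncation of
its SVD, H ~ sum_l u_l v_l^H (singular values absorbed into v_l), turns the
Hadamard-product encoding operator F o H into L diagonal-scaled applications
of the plain Fourier operator -- the entire computational point of the
factorization.  The truncation error is governed by the Eckart-Young
theorem: ||H - H_L||_F = sqrt(sum_{l>L} sigma_l^2).

The factorization is computed with a seeded randomized SVD (Gaussian range
finder with oversampling and power iterations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "LowRankFactors",
    "randomized_svd",
    "truncation_error",
    "select_rank",
]


@dataclass
class LowRankFactors:
    """Truncated SVD of one interleaf's H: U (N_k, L_max), V (N, L_max).

    Columns of U are orthonormal left singular vectors (temporal basis);
    columns of V are right singular vectors scaled by their singular values
    (spatial basis), so that ``H ~ U[:, :L] @ V[:, :L].conj().T``.
    """

    U: np.ndarray
    V: np.ndarray
    sigma: np.ndarray
    L: int

    def __post_init__(self):
        if self.U.shape[1] != self.V.shape[1] or self.U.shape[1] != self.sigma.size:
            raise ValueError("inconsistent factor shapes")
        if not 1 <= self.L <= self.L_max:
            raise ValueError("L must lie in [1, L_max]")

    @property
    def L_max(self) -> int:
        return self.sigma.size

    def with_rank(self, L: int) -> "LowRankFactors":
        if not 1 <= L <= self.L_max:
            raise ValueError(f"L must lie in [1, {self.L_max}]")
        return LowRankFactors(self.U, self.V, self.sigma, L)

    def reconstruct(self, L: Optional[int] = None) -> np.ndarray:
        """Materialize the rank-L approximation (small problems only)."""
        L = self.L if L is None else L
        return self.U[:, :L] @ self.V[:, :L].conj().T


def randomized_svd(
    H,
    L_max: int,
    oversample: int = 10,
    n_power_iter: int = 2,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> LowRankFactors:
    """Top-L_max singular triplets of H via a Gaussian range finder.

    ``H`` may be a dense complex array or any object exposing ``shape``,
    ``__matmul__`` on (n, p) blocks and a ``conj().T`` route (ndarray
    semantics); power iterations with QR re-orthonormalization keep the
    range estimate accurate for slowly decaying spectra.

    A seed (or Generator) is required so factorizations are reproducible.
    """
    if rng is None:
        if seed is None:
            raise ValueError("randomized_svd requires a seed (or an explicit rng)")
        rng = np.random.default_rng(seed)
    n_k, n = H.shape
    if L_max > min(n_k, n):
        raise ValueError(f"L_max={L_max} exceeds min(H.shape)={min(n_k, n)}")
    p = min(L_max + oversample, min(n_k, n))

    omega = rng.standard_normal((n, p)) + 1j * rng.standard_normal((n, p))
    Y = H @ omega
    Q, _ = np.linalg.qr(Y)
    Hc = H.conj().T if isinstance(H, np.ndarray) else None
    for _ in range(n_power_iter):
        Z = Hc @ Q if Hc is not None else H.rmatmat(Q)
        Z, _ = np.linalg.qr(Z)
        Y = H @ Z
        Q, _ = np.linalg.qr(Y)
    B = (Hc @ Q).conj().T if Hc is not None else H.rmatmat(Q).conj().T  # (p, n)
    Ub, s, Vh = np.linalg.svd(B, full_matrices=False)
    U = (Q @ Ub)[:, :L_max]
    s = s[:L_max]
    V = Vh[:L_max].conj().T * s[None, :]
    return LowRankFactors(U=U, V=V, sigma=s, L=L_max)


def truncation_error(factors: LowRankFactors, L: int) -> float:
    """Frobenius error of the rank-L truncation: sqrt(sum_{l>L} sigma_l^2).

    Exact for the computed L_max-term factorization (singular values beyond
    L_max are not represented and therefore not counted).
    """
    if not 0 <= L <= factors.L_max:
        raise ValueError(f"L must lie in [0, {factors.L_max}]")
    tail = factors.sigma[L:]
    return float(np.sqrt(np.sum(tail * tail)))


def select_rank(
    recon_at: Callable[[int], np.ndarray],
    L_max: int,
    threshold: float = 0.02,
    reference: Optional[np.ndarray] = None,
    candidates: Optional[Sequence[int]] = None,
) -> tuple[int, np.ndarray]:
    """Smallest shared rank L whose reconstruction is within ``threshold``
    NRMSE of the full-rank (L = L_max) reconstruction.

    ``recon_at(L)`` must return the complex image reconstructed with rank L;
    one L is selected and shared across all interleaves.  Returns ``(L,
    nrmse_curve)`` over the candidate ranks; if the threshold is unreachable
    the full rank is returned (with the curve available for inspection).
    """
    from .recon import nrmse  # local import to avoid a cycle

    if reference is None:
        reference = recon_at(L_max)
    Ls = list(candidates) if candidates is not None else list(range(1, L_max + 1))
    curve = np.empty(len(Ls))
    chosen = None
    for idx, L in enumerate(Ls):
        curve[idx] = nrmse(reference, recon_at(L))
        if chosen is None and curve[idx] < threshold:
            chosen = L
            if candidates is None:
                curve = curve[: idx + 1]
                break
    if chosen is None:
        import warnings

        warnings.warn(
            f"NRMSE threshold {threshold} unreachable at L_max={L_max}; "
            "returning full rank",
            stacklevel=2,
        )
        chosen = L_max
    return chosen, curve
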