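"""Non-uniform Fourier operator F for one interleaf.

Evaluates the Fourier sum ``y_t = sum_rho exp(-j k(t) . r_rho) x_rho`` (and
its adjoint) exactly, by materializing the (N_k, N) phasor matrix in row
blocks.  At the grid sizes this package targets (<= 128 x 128 with a few
thousand samples per interleaf) exact evaluation is both faster to set up
and more accurate than an approximate gridding transform, and the matrix is
reused across coils and iterations.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = ["NonuniformFourier", "dense_dft_matrix"]

_MAX_DENSE_ENTRIES = 1 << 26  # guard: ~1 GiB of complex128


def dense_dft_matrix(k: np.ndarray, coords: np.ndarray, sign: float = -1.0) -> np.ndarray:
    """Dense phasor matrix exp(sign * j * k . r), shape (N_k, N)."""
    phase = k[:, :2] @ coords[:, :2].T if np.all(k[:, 2] == 0) and np.all(coords[:, 2] == 0) else k @ coords.T
    return np.exp(1j * sign * phase)


class NonuniformFourier:
    """Exact non-uniform DFT with cached matrix and conjugate-pair adjoint.

    Parameters
    ----------
    k : (N_k, 3) sampling locations, rad/m (logical frame by convention).
    coords : (N, 3) voxel centers, meters (logical frame).
    sign : -1 for the forward-encode convention exp(-j k.r) (default).
    """

    def __init__(self, k: np.ndarray, coords: np.ndarray, sign: float = -1.0):
        self.k = np.asarray(k, dtype=float)
        self.coords = np.asarray(coords, dtype=float)
        if self.k.ndim != 2 or self.k.shape[1] != 3:
            raise ValueError("k must have shape (N_k, 3)")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if self.k.shape[0] * self.coords.shape[0] > _MAX_DENSE_ENTRIES:
            raise ValueError(
                "problem too large for the dense non-uniform DFT operator "
                f"({self.k.shape[0]} x {self.coords.shape[0]} entries)"
            )
        self.sign = float(sign)
        self._matrix: Optional[np.ndarray] = None

    @property
    def n_samples(self) -> int:
        return self.k.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = dense_dft_matrix(self.k, self.coords, self.sign)
        return self._matrix

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Image -> k-space samples.  Accepts (N,) or (N, m) stacks."""
        return self.matrix @ x

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """k-space samples -> image (conjugate transpose of forward)."""
        return self.matrix.conj().T @ y
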