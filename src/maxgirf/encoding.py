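"""The higher-order encoding operator E_i = F_i o H_i per interleaf.

``F_i`` is the non-uniform Fourier matrix built from the *logical*-frame
trajectory and grid; ``H_i`` collects all remaining phase (static
off-resonance and concomitant fields) evaluated at *physical*-frame voxel
positions.  The multi-coil forward model is ``d_ic = E_i S_c m + n_ic`` and
the adjoint is ``sum_ic S_c^H E_i^H d_ic``.

Two representations of H are supported:

* ``dense`` -- the (N_k, N) phase matrix is materialized and E_i = F_i * H_i
  is cached; exact, used for small problems and as the oracle;
* ``lowrank`` -- H_i ~ sum_l u_l v_l^H, and E_i x is evaluated as L
  diagonal-scaled Fourier applications
  ``sum_l diag(u_l) F_i diag(v_l^*) x`` (adjoint mirrored), which is the
  identity that makes the method tractable at scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from .concomitant import HigherOrderPhase
from .fourier import NonuniformFourier
from .geometry import LOGICAL, FrameError, SpatialGrid, Trajectory
from .lowrank import LowRankFactors

__all__ = [
    "KSpaceData",
    "CoilMaps",
    "EncodingOperator",
    "build_dense_H",
    "MAX_DENSE_H_ENTRIES",
]

MAX_DENSE_H_ENTRIES = 1 << 26


@dataclass
class KSpaceData:
    """Multi-coil k-space samples, shape (N_i, N_c, N_k)."""

    samples: np.ndarray
    dwell_s: float
    noise_sigma: Optional[float] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 3:
            raise ValueError("samples must have shape (N_i, N_c, N_k)")

    @property
    def n_interleaves(self) -> int:
        return self.samples.shape[0]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[2]


@dataclass
class CoilMaps:
    """Receive sensitivities, shape (N_c, N), unitless."""

    maps: np.ndarray

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=complex)
        if self.maps.ndim != 2 or self.maps.shape[0] < 1:
            raise ValueError("maps must have shape (N_c, N) with N_c >= 1")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("coil maps must be finite")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @classmethod
    def uniform(cls, n_voxels: int) -> "CoilMaps":
        return cls(np.ones((1, n_voxels), dtype=complex))


def build_dense_H(phase: HigherOrderPhase) -> List[np.ndarray]:
    """Materialize H_i = exp(-j phi~_i) for every interleaf.

    Guarded against oversized problems; callers that exceed the guard should
    use the low-rank representation instead.
    """
    n_entries = phase.n_samples * phase.n_voxels
    if n_entries > MAX_DENSE_H_ENTRIES:
        raise MemoryError(
            f"dense H would hold {n_entries} entries (> {MAX_DENSE_H_ENTRIES}); "
            "use the low-rank operator mode"
        )
    return [np.exp(-1j * phase.phase_matrix(i)) for i in range(phase.n_interleaves)]


class EncodingOperator:
    """Forward/adjoint contract for the stacked multi-interleaf model.

    forward: image (N,) -> data (N_i, N_c, N_k)
    adjoint: data (N_i, N_c, N_k) -> image (N,)   [exact conjugate transpose]
    """

    def __init__(
        self,
        nuffts: Sequence[NonuniformFourier],
        coilmaps: CoilMaps,
        H: Union[None, Sequence[np.ndarray], Sequence[LowRankFactors]] = None,
        L: Optional[int] = None,
    ):
        self.nuffts = list(nuffts)
        self.coilmaps = coilmaps
        self.n_voxels = self.nuffts[0].n_voxels
        if coilmaps.maps.shape[1] != self.n_voxels:
            raise ValueError("coil maps do not match the grid size")
        self._dense_E: Optional[List[np.ndarray]] = None
        self._factors: Optional[List[LowRankFactors]] = None
        if H is None:
            self.mode = "fourier"
        elif isinstance(H[0], LowRankFactors):
            self.mode = "lowrank"
            self._factors = list(H)
            if L is not None:
                self._factors = [f.with_rank(L) for f in self._factors]
            if len(self._factors) != len(self.nuffts):
                raise ValueError("one factorization per interleaf required")
        else:
            self.mode = "dense"
            dense_H = [np.asarray(h) for h in H]
            if len(dense_H) != len(self.nuffts):
                raise ValueError("one H per interleaf required")
            for h, f in zip(dense_H, self.nuffts):
                if h.shape != (f.n_samples, self.n_voxels):
                    raise ValueError("H shape must be (N_k, N)")
            # cache E_i = F_i * H_i once; reused by every matvec
            self._dense_E = [f.matrix * h for f, h in zip(self.nuffts, dense_H)]

    # -- construction helpers -------------------------------------------------

    @classmethod
    def build(
        cls,
        traj_L: Trajectory,
        grid_L: SpatialGrid,
        coilmaps: CoilMaps,
        phase: Optional[HigherOrderPhase] = None,
        mode: str = "dense",
        L: Optional[int] = None,
        svd_seed: int = 0,
        L_max: int = 50,
        oversample: int = 10,
        n_power_iter: int = 2,
    ) -> "EncodingOperator":
        """Build the operator from logical-frame trajectory/grid and the
        physical-frame higher-order phase.

        Frame discipline is enforced here: the Fourier part refuses anything
        but logical-frame inputs (the higher-order phase container is built
        from physical-frame quantities by construction).
        """
        if traj_L.frame != LOGICAL or grid_L.frame != LOGICAL:
            raise FrameError("Fourier encoding requires logical-frame trajectory and grid")
        nuffts = [
            NonuniformFourier(traj_L.k_samples[i], grid_L.coords)
            for i in range(traj_L.n_interleaves)
        ]
        if phase is None:
            return cls(nuffts, coilmaps, None)
        if phase.n_samples != traj_L.n_samples or phase.n_voxels != grid_L.n_voxels:
            raise ValueError("phase dimensions do not match trajectory/grid")
        dense_H = build_dense_H(phase)
        if mode == "dense":
            return cls(nuffts, coilmaps, dense_H)
        if mode == "lowrank":
            from .lowrank import randomized_svd

            L_max = min(L_max, phase.n_samples, phase.n_voxels)
            factors = [
                randomized_svd(h, L_max, oversample, n_power_iter, seed=svd_seed + i)
                for i, h in enumerate(dense_H)
            ]
            return cls(nuffts, coilmaps, factors, L=L)
        raise ValueError("mode must be 'dense' or 'lowrank'")

    # -- properties -----------------------------------------------------------

    @property
    def n_interleaves(self) -> int:
        return len(self.nuffts)

    @property
    def n_coils(self) -> int:
        return self.coilmaps.n_coils

    @property
    def factors(self) -> Optional[List[LowRankFactors]]:
        return self._factors

    @property
    def L(self) -> Optional[int]:
        return self._factors[0].L if self._factors is not None else None

    def with_rank(self, L: int) -> "EncodingOperator":
        """Same operator at a different shared truncation rank."""
        if self._factors is None:
            raise ValueError("with_rank applies to low-rank operators only")
        op = EncodingOperator(self.nuffts, self.coilmaps, self._factors, L=L)
        return op

    # -- forward / adjoint ----------------------------------------------------

    def _interleaf_forward(self, i: int, x: np.ndarray) -> np.ndarray:
        """E_i applied to a stack of images, (N, m) -> (N_k, m)."""
        if self.mode == "fourier":
            return self.nuffts[i].forward(x)
        if self.mode == "dense":
            return self._dense_E[i] @ x
        f = self._factors[i]
        out = None
        for l in range(f.L):
            term = f.U[:, l : l + 1] * self.nuffts[i].forward(f.V[:, l : l + 1].conj() * x)
            out = term if out is None else out + term
        return out

    def _interleaf_adjoint(self, i: int, y: np.ndarray) -> np.ndarray:
        """E_i^H applied to a stack of data vectors, (N_k, m) -> (N, m)."""
        if self.mode == "fourier":
            return self.nuffts[i].adjoint(y)
        if self.mode == "dense":
            return self._dense_E[i].conj().T @ y
        f = self._factors[i]
        out = None
        for l in range(f.L):
            term = f.V[:, l : l + 1] * self.nuffts[i].adjoint(f.U[:, l : l + 1].conj() * y)
            out = term if out is None else out + term
        return out

    def forward(self, m: np.ndarray) -> np.ndarray:
        """d_ic = E_i S_c m for every interleaf and coil (noiseless)."""
        m = np.asarray(m).reshape(self.n_voxels)
        weighted = self.coilmaps.maps.T * m[:, None]  # (N, N_c)
        out = np.empty(
            (self.n_interleaves, self.n_coils, self.nuffts[0].n_samples), dtype=complex
        )
        for i in range(self.n_interleaves):
            out[i] = self._interleaf_forward(i, weighted).T
        return out

    def adjoint(self, d: np.ndarray) -> np.ndarray:
        """sum_i sum_c S_c^H E_i^H d_ic -> image (N,)."""
        d = np.asarray(d, dtype=complex)
        if d.shape != (self.n_interleaves, self.n_coils, self.nuffts[0].n_samples):
            raise ValueError("data shape does not match the operator")
        acc = np.zeros(self.n_voxels, dtype=complex)
        for i in range(self.n_interleaves):
            imgs = self._interleaf_adjoint(i, d[i].T)  # (N, N_c)
            acc += np.sum(self.coilmaps.maps.conj().T * imgs, axis=1)
        return acc

    def dense_matrix(self, i: int) -> np.ndarray:
        """Explicit E_i (oracle use; dense mode only)."""
        if self.mode == "dense":
            return self._dense_E[i]
        if self.mode == "fourier":
            return self.nuffts[i].matrix
        return self.nuffts[i].matrix * self._factors[i].reconstruct()
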