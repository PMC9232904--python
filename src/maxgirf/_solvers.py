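"""Shared conjugate-direction least-squares solver (CGLS).

CGLS generates the same Krylov iterates as LSQR in exact arithmetic; it is
used wherever the package needs a linear least-squares solve with access to
the per-iteration residual history.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Tuple

import numpy as np


def cgls(
    fwd: Callable[[np.ndarray], np.ndarray],
    adj: Callable[[np.ndarray], np.ndarray],
    b: np.ndarray,
    x0: Optional[np.ndarray] = None,
    max_iter: int = 15,
    tol: float = 1e-5,
    damp: float = 0.0,
) -> Tuple[np.ndarray, List[float], bool]:
    """Minimize ||b - A x||^2 + damp^2 ||x||^2.

    Stops when the normal-equation residual ||A^H(b - Ax) - damp^2 x|| falls
    below ``tol`` times its initial value.  Returns (x, residual_history,
    converged); the history holds ||b - A x|| per accepted iterate.
    """
    if x0 is None:
        s = adj(b)
        x = np.zeros_like(s)
        r = np.asarray(b, dtype=complex).copy()
    else:
        x = np.asarray(x0, dtype=complex).copy()
        r = b - fwd(x)
        s = adj(r) - damp * damp * x
    p = s.copy()
    gamma = float(np.vdot(s, s).real)
    gamma0 = gamma
    residuals = [float(np.linalg.norm(r))]
    if gamma0 == 0.0:
        return x, residuals, True
    converged = False
    for _ in range(max_iter):
        q = fwd(p)
        qq = float(np.vdot(q, q).real) + damp * damp * float(np.vdot(p, p).real)
        if qq == 0.0:
            break
        alpha = gamma / qq
        x = x + alpha * p
        r = r - alpha * q
        residuals.append(float(np.linalg.norm(r)))
        s = adj(r) - damp * damp * x
        gamma_new = float(np.vdot(s, s).real)
        if np.sqrt(gamma_new / gamma0) < tol:
            converged = True
            break
        p = s + (gamma_new / gamma) * p
        gamma = gamma_new
    return x, residuals, converged
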