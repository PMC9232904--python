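"""Low-rank factorization of the higher-order encoding matrix.

The unit-modulus phase matrix H is strongly compressible; truncating its
SVD to L components turns the encoding operator into L diagonal-scaled
Fourier applications.  This script sweeps L on a small simulated scan and
prints the NRMSE of each truncated conjugate-phase reconstruction against
the full-rank one, plus the smallest L inside the 2% criterion.
"""

import numpy as np

import maxgirf as mg

scenario = mg.desk_scenario(
    orientation="sagittal", offset_m=0.05, B0=0.55, matrix=32,
    n_interleaves=4, n_coils=3, deltaf_peak_Hz=100.0,
)
L, curve = mg.rank_study(scenario, L_max=16, threshold=0.02)

print("rank L -> NRMSE vs full-rank reconstruction:")
for i, v in enumerate(curve[:12], start=1):
    marker = "  <- selected" if i == L else ""
    print(f"  L={i:2d}  {v:.4f}{marker}")
print(
    f"\nL = {L} truncated components reproduce the full-rank image within "
    "2%; the reconstruction cost scales linearly with L."
)
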