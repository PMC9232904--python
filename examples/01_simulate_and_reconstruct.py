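"""Simulate a spiral acquisition off isocenter and reconstruct it.

Builds a 32 x 32 sagittal spiral scan 100 mm off isocenter at 0.55 T with
off-resonance and concomitant fields, then reconstructs it twice: once with
the plain Fourier/SENSE model (no higher-order phase) and once with the
full higher-order encoding model.  The two NRMSE values quantify how much
image error the concomitant-field and off-resonance correction removes.
"""

import maxgirf as mg

scenario = mg.desk_scenario(
    orientation="sagittal", offset_m=0.10, B0=0.55, matrix=32,
    n_interleaves=4, n_coils=3, deltaf_peak_Hz=100.0, sim_oversample=2,
)

plain = mg.prepare_encoding(
    scenario.gradients, scenario.geom, scenario.grid, scenario.coilmaps
)
uncorrected = mg.reconstruct(plain, scenario.data, method="lsq")

corrected_setup = mg.prepare_encoding(
    scenario.gradients, scenario.geom, scenario.grid, scenario.coilmaps,
    deltaf_Hz=scenario.deltaf_Hz, model=scenario.model,
)
corrected = mg.reconstruct(corrected_setup, scenario.data, method="lsq")

e_plain = mg.nrmse(scenario.truth, uncorrected.image)
e_corr = mg.nrmse(scenario.truth, corrected.image)
print(f"uncorrected (Fourier/SENSE) NRMSE : {e_plain:.4f}")
print(f"higher-order corrected NRMSE      : {e_corr:.4f}")
print(
    "The corrected reconstruction removes the blur that off-resonance and "
    "concomitant fields add on top of the discretization floor."
)
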