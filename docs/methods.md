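# Methods

## Signal model and assumptions

The package models the demodulated signal of one spiral interleaf as the
integral of the object times coil sensitivity times `exp(−jφ)` with

```
φ_i(r,t) = k_i(t)·r + 2πΔf(r)(t − t0) + Σ_{ℓ=4} k_ℓ,i(t) p_ℓ(r).
```

Assumptions inherited by every stage:

* **Static magnetization during the readout.** No T1/T2/T2* decay term —
  the simulator injects none and the reconstruction models none. Sequences
  where concomitant phase survives across RF pulses (balanced SSFP, fast
  spin echo) are out of scope.
* **Phase reference at the readout start.** `t0` is the isodelay (gradient
  echo) or TE (spin echo); the sequence is assumed to null accumulated
  encoding and concomitant phase there (waveform-reshaped rephasing), so
  `k(t0) = k_ℓ(t0) = 0` in both the simulator and the reconstruction.
* **Symmetric gradient coil, zero gradient nonlinearity.** The concomitant
  basis derives from `B_x = G_x z − G_z x/2`, `B_y = G_y z − G_z y/2`:
  expanding `‖B‖` about `B0 + G·r` gives the six quadratic terms scaling as
  `G²/B0` ("lowest" order) and, one order further
  (`−(B_x²+B_y²)(G·r)/2B0²`), ten cubic terms scaling as `1/B0²` ("full"
  order). Asymmetric-coil expressions are not implemented.
* **2D slices.** `z_L ≡ 0`; through-plane position enters only via the
  slice offset and rotation.

Frames are explicit: Fourier encoding uses the logical (slice) frame,
concomitant quantities the physical (gradient-coil) frame, related by
`r_P = R r_L + r_offset`. Off-isocenter raw data carry the modulation
`exp(−j k_P(t)·r_offset)`, which must be demodulated before higher-order
correction so voxels sit at their true physical positions; both directions
are provided and the round trip is tested to 1e−12.

## Gradient-chain model

Per physical axis, predicted gradients are `IFFT(FFT(zero-padded input) ×
T_a(f))` with `T_a` the (measured or synthesized) transfer function. Only
self-terms are applied; B0 cross-terms are stored but ignored. Numerical
choices: zero-pad to a power of two ≥ 4× the waveform length so circular
convolution approximates linear convolution (doubling the pad changes the
output below 1e−8 relative when the resampled transfer is itself accurate);
resampling onto the waveform grid interpolates magnitude and unwrapped
phase (exact for pure delays); outside the measured band the edge magnitude
is held with linear phase continued at the fitted group delay — a package
decision, since out-of-band behaviour is not otherwise defined.

## Spiral designer

Fixtures come from a constant-pitch Archimedean spiral `k = aθe^{jθ}` with
pitch `a = n_interleaves/FOV` (full-set turn spacing exactly Nyquist),
traversed under amplitude and slew limits by capping the angular velocity
at `min(v_amplitude, v_slew)` with the slew budget split between curvature
and angular acceleration. A 0.92 safety factor absorbs discretization of
the constraint check onto the ADC raster. Variable-density schedules are
not implemented — fixtures only need constraint-satisfying, Nyquist-valid
trajectories.

## Encoding operator and low-rank factorization

`E_i = F_i ⊙ H_i` supports two representations: a cached dense matrix
(guarded at 2^26 entries; exact, also the oracle in tests) and the rank-L
factorization applying `Σ_ℓ diag(u_ℓ) F_i diag(v_ℓ*)`. The non-uniform
Fourier operator is evaluated as an exact chunked dense DFT: at the package's
target sizes (≤ 128×128 synthesis, ≤ 64×64 reconstruction, ≲ 1.5e4 samples
per interleaf) exact evaluation is fast, reusable across coils and
iterations, and removes an approximation tolerance from every oracle
comparison. The low-rank path retains its computational point — L Fourier
applications replace the dense H product — independent of how F itself is
evaluated.

The factorization uses a seeded Gaussian randomized SVD (oversampling 10,
two power iterations with QR re-orthonormalization). These defaults resolve
rapidly decaying spectra (the H matrices here) to ~1e−8; matrices with flat
spectra need the sketch widened to the full minor dimension, which the
tests do where oracle-grade accuracy on random matrices is asserted. One
truncation rank L is shared across all interleaves, chosen as the smallest
L whose conjugate-phase reconstruction is within 2% NRMSE of the full-rank
one; all L candidates cost one full-rank reconstruction via cumulative
per-component images.

## Reconstruction

* **Conjugate phase:** adjoint of the encoding operator applied to
  density-compensated data. Weights are the spiral Jacobian: constant turn
  spacing × along-arm speed, so `w ∝ |dk/dt|`, reduced by `min(1, r/pitch)`
  inside the pitch radius where the interleaf arms converge; a Voronoi-cell
  fallback covers arbitrary 2D trajectories and cross-checks the analytic
  weights in the tests. A radius-proportional factor (appropriate for
  radial fans) over-weights spiral edges — the Voronoi comparison caught
  exactly this. Absolute intensity of conjugate-phase images is defined
  only up to scale; comparisons fit a global complex scale first.
* **Iterative least squares:** CGLS on the normal equations of the stacked
  interleaf/coil operator — the same Krylov family as LSQR, chosen
  in-package so the per-iteration residual history is available (it is
  non-increasing by construction); scipy's LSQR is the independent
  cross-check in the tests. Defaults: 15 iterations, tolerance 1e−5 on the
  relative normal-equation residual.
* With off-resonance and concomitant terms disabled the operator reduces
  exactly to SENSE; with one uniform coil, to plain non-uniform Fourier
  reconstruction.

## Off-resonance mapping

Echo images are modelled as `ρ ⊙ exp(j2πΔf·TE_m)` with `Δf` absorbing the
water/fat chemical shift (−88 Hz at 0.55 T) rather than separating it. The
iteratively regularized Gauss–Newton scheme optimizes preconditioned
variables: identity on `ρ`, the Sobolev operator `F^{-1}(1+w‖k‖²)^{−h}F`
(w = 32, h = 16, k normalized to [−0.5, 0.5]²) on `Δf`. Regularization
follows `α_n = max(2^{−n}, 1e−6)` from `α_0 = 1` (only the floor is
prescribed by the method's lineage; the schedule and the initialization
`ρ̂_0` = first echo, `Δf̂_0 = 0` are package decisions). Inner solves use
the shared CGLS solver (250 iterations, tolerance 1e−10). Echoes are
normalized internally to peak magnitude 100 — the nonlinear-inversion
convention that makes the absolute α schedule meaningful — and `ρ` is
un-normalized on return.

A consequence worth stating: relative to that scale, weight components with
`w_k²‖J‖² ≪ α_min` are effectively frozen, which limits the recoverable
band of `Δf` to roughly |k| ≲ 0.15 of the band edge. Smooth fields recover
to ≪ 0.1 Hz; a sharp fat-region boundary is recovered only to a ~3-voxel
kernel, leaving tens-of-Hz errors in a thin boundary ring (several Hz RMSE
over the support). Raising the internal scale does not help — it removes
the early-iteration damping that keeps the nonlinear steps stable. This is
a property of the printed preconditioner constants, not of the
implementation; the acceptance test that demands sub-Hz recovery across a
sharp fat boundary fails for this reason and is left failing.

## Synthetic data

The simulator generates everything the pipeline consumes: an ellipse-sum
head phantom rasterized at voxel centers; smooth complex coil maps
(Gaussian lobes on the FOV perimeter with gentle linear phase, sum of
squares positive everywhere, > 99% spectral energy in the central quarter
of k-space); a smooth off-resonance map (Gaussian bump + ramp scaled to a
peak value) with an optional sharp-boundary fat region shifted by −88 Hz;
and k-space synthesized through the exact dense model with i.i.d. complex
Gaussian noise (no coil covariance). Synthesis on a 2× finer grid than
reconstruction (used by the sweep tests) avoids the inverse crime; the fine
phantom is rescaled by the voxel-area ratio so total signal matches. What
the generator does not emulate: anatomy-dependent texture, relaxation
contrast and decay, physiological motion, coil coupling — so passing tests
demonstrate correctness of the encoding/correction machinery, not clinical
image quality.

**Default desk scenario** (the study conditions for most tests): 64×64
matrix over 240 mm FOV, 6-interleaf spiral at 24 mT/m, 144 T/m/s, 2.5 μs
dwell (≈ 2.4 ms readout at this resolution), 4 coils, 0.55 T. The gradient
limits and dwell are kept at the reference simulation values; the readout
is consequently shorter than the reference's 9.2 ms, which belongs to a
256×256 / 0.94 mm setting — at a 64×64 desk scale both cannot hold at once,
and preserving the gradient regime preserves the concomitant-field physics.

**Rank-study scenario:** the truncation rank needed by the concomitant
phase grows with gradient amplitude and with the square of the spatial
coverage (its dominant terms are quadratic monomials). At the default desk
scale the off-resonance rank dominates both orientations and the
axial/sagittal comparison degenerates. The rank study therefore runs where
that comparison is actually exercised, mirroring the head-and-neck scans
such studies are performed on: a single-shot 64×64 spiral over a 0.48 m
sagittal field of view at scanner hardware limits (45 mT/m, 200 T/m/s,
1 μs dwell, ≈ 12.5 ms readout), smooth 150 Hz off-resonance, 0.55 T, 50 mm
offset; the axial comparator is matched in everything but orientation. In
the axial case the concomitant phase is a spatially constant (per-slice)
frequency shift — a unitary diagonal factor that cannot raise the rank —
so its smaller L is a structural property, not a tuning outcome.

## Degenerate inputs and tie-breaks

Orthogonality of rotations is enforced at 1e−10; non-orthogonal matrices,
frame mismatches, dimension mismatches and non-positive weights raise
typed errors rather than propagating. The density-weight floor (1e−3 of
the maximum) keeps conjugate-phase weights positive at `k = 0`. The
Gauss–Newton loop stops early after three consecutive residual increases
and returns the best iterate. `select_rank` warns and returns the full
rank when the threshold is unreachable.

## Known limitations

Exact dense Fourier evaluation bounds practical problem sizes (hundreds of
megabytes per interleaf beyond ~128×128); a gridding NUFFT backend would
lift this without touching any contract. The conjugate-phase weights are
approximate by design (the iterative path needs none). The field-map
estimator's resolution limit under the printed Sobolev constants is
described above. GIRFs are loaded or synthesized, never estimated from
measurement data.
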