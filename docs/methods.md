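# Methods

`nlinvpp` reconstructs a 2D Cartesian multi-coil MR acquisition by jointly
estimating the complex image ρ(r) and the coil sensitivity maps c_i(r), and
detects and removes *phase poles* — spurious phase singularities that the
joint estimation can introduce — both inside the iteration and post hoc on
externally calibrated coil maps.

## Signal model and conventions

The measured k-space of coil i is

    y_i(k) = P F (c_i ⊙ ρ) + n_i,

with F the centered, unitary 2D FFT, P a binary Cartesian sampling mask
containing a fully sampled central auto-calibration (AC) block, ⊙ the
pointwise product, and n complex white Gaussian noise (pre-whitened, iid
across coils; `noise_sigma` is the standard deviation per real/imaginary
component). The field of view is the unit square: pixel (ix, iy) of an
nx × ny grid sits at ((ix+0.5)/nx − 0.5, (iy+0.5)/ny − 0.5), so lengths
quoted as FoV fractions convert to pixels by multiplying with the grid size.
k-space is stored centered with the zero frequency at index (nx//2, ny//2).
Interchange with other toolboxes uses the CFL format (an ASCII `.hdr` with a
dimension line plus a column-major little-endian complex-float32 `.cfl`).

Only the product c_i ⊙ ρ is observable: any unit-modulus field ϑ(r) maps a
solution (ρ, c) to an equally consistent solution (ϑρ, ϑ̄c). This *gauge
ambiguity* is the origin of the artifact this package addresses.

## Nonlinear inversion (NLINV)

The solver minimizes

    ‖y − P F((W c̃) ⊙ ρ)‖² + α‖ρ‖² + α‖c̃‖²,

where W is a per-coil k-space low-pass with radial weight
w(k) = (1 + a‖k‖²)^(−b) (FoV-normalized k ∈ [−0.5, 0.5]²; defaults a = 220,
b = 16, following the established NLINV convention — the weight shape is
config-exposed). The penalty on the preconditioned variables c̃ = W⁻¹c is a
Sobolev norm of c, so the estimated coils are forced to be smooth, which is
what makes fully self-calibrated estimation from small AC regions work.

The outer loop is an iteratively regularized Gauss–Newton method: the forward
map is linearized around the iterate and the update solves

    (DFᴴDF + αI) δx = DFᴴ(y − F(x)) + α(x₀ − x)

by conjugate gradients (at most `cg_iters` = 50 iterations or relative
residual `cg_tol` = 1e-6; these are solver defaults, not claims about any
reference implementation). The penalty shrinks the *new* iterate toward the
initialization x₀ = (ρ ≡ 1, c̃ ≡ 0), which favors real-valued images; shrinking
toward zero instead provably stalls on this bilinear problem, because at
c = 0 the image receives no data gradient and is annihilated by the penalty,
and then vice versa. α decays as α(k) = max(α_min, q^k) with q = 0.5 and
α_min = 0.001 over 12 Gauss–Newton steps. The data is normalized to
‖y‖₂ = 100 first (an empirically good operating point for 2D problems) and
the image is un-scaled at the end. The final pair is rescaled so the coils
have unit root-sum-of-squares (RSS) wherever nonzero and the image carries
the RSS magnitude (the common ESPIRiT-style normalization); the products
c_i ⊙ ρ are invariant under this step. `rss_normalize=False` exposes the raw
coil magnitudes, which is how the black-hole diagnostics below are computed.

## Phase poles, detection, correction

A phase pole is a point where the phase of a complex field is undefined and
the loop integral of the phase gradient around it is a nonzero multiple of
2π; equivalently the field's values wind around the complex origin along the
loop. For a smooth field the amplitude must vanish at the pole. Since the
coil penalty enforces smooth coils, a spurious image pole compensated by
conjugate coil poles drives the coil magnitude — and with it the regularized
reconstruction — to zero at that point: a "black hole". Such configurations
are data-consistent local minima of the NLINV objective.

Winding numbers are computed discretely: the loop is a circle of diameter d
(default 0.05 FoV) rounded to grid points — N = max(8, ⌈πd_px⌉) angles,
consecutive duplicates removed — and the sum of principal-value phase
increments Arg ∈ (−π, π] along the loop, divided by 2π, is rounded to the
nearest integer (the sum is within 1/2 of an integer for clean fields, and
the averaging step below assumes integer per-coil maps). If the field is
exactly zero at a loop point the phase is undefined and the winding number is
defined as 0; loops clipped by the FoV boundary also report 0, so poles
within d/2 of the edge are a known blind zone. Diameters below 2 px
degenerate under rounding and are implemented as the four-neighbour
one-pixel loop.

Detection runs on the coil maps, not the image — low-signal image regions
produce spurious windings, while the coils are smooth and noise-free:

1. per coil, the winding map S_i(r) on the d-circle around every pixel;
2. weights w_i(r) = |c_i(r)|², which suppress *genuine* single-coil
   singularities (their own amplitude vanishes there);
3. the weighted average S̄(r) = Σ w_i S_i / Σ w_i (zero where all weights
   vanish) — a pole shared by all coils keeps |S̄| ≈ 1, a pole in one of
   n comparable-magnitude coils is bounded near 1/n;
4. threshold |S̄| > t with t = 1/2 (strict inequality; the choice only
   matters at exactly t);
5. morphological closing with a disk of diameter d_closing = d merges split
   detections so one pole is never corrected twice (the disk footprint is
   built directly from the pixel radius because library elements only come
   in integer radii);
6. connected components (8-connectivity by default, 4 available); each
   yields one pole at the unweighted centroid of its pixels, with the sign
   of the mean of S̄ over the component — the winding observed in the
   *coils*; the compensated image pole has the opposite winding.

The correction field is the product of unit-magnitude phase vortices
ϑ(r) = Π_j ((r−r_j)_x + i s_j (r−r_j)_y)/‖r−r_j‖, one per detected pole,
followed by a global phase chosen so that ⟨ρ, ϑ⊙ρ⟩ is real and positive —
i.e. ϑ is rotated by the normalized image-power-weighted average of ϑ̄, which
changes the image phase as little as possible where the signal is strong.
Inside the solver the image is multiplied by ϑ and the coils by ϑ̄, the coil
side passing through natural coordinates: c̃ ← W⁺(ϑ̄ ⊙ W c̃) with the
regularized pseudoinverse W⁺ = w/(w² + ε), ε = 1e-6 (capping the worst-case
amplification at 1/(2√ε); exact division is numerically explosive because w
spans ~33 orders of magnitude across k-space). Detection runs once, after 8
of the 12 Gauss–Newton steps — late enough that the iterate has settled,
early enough that the remaining steps refine the corrected estimate
(`detect_every` enables repeated detection, which also resolves two same-sign
poles merged into one detection). Because W⁺ necessarily band-limits the
vortex-multiplied coils, the data residual rises transiently at the
correction and recovers over the remaining steps; this is expected behavior,
not a failure.

**Reference transport.** The α-penalty reference x₀ is a gauge-dependent
quantity. When a correction is applied, the solver transports x₀ by the same
vortex pair; otherwise a reference containing the pole (as when the solver is
deliberately started inside a pole gauge) pulls the refinement straight back
into the minimum just corrected. With the standard x₀ = (1, 0) the transport
only acts through the small late-iteration α.

**External mode.** Coil stacks calibrated elsewhere (e.g. ESPIRiT maps using
the first coil as phase reference) carry poles at the *identical* pixel in
every coil, so detection uses the one-pixel four-neighbour loop and skips the
closing. The coils are multiplied by ϑ̄ and the combined image (if given) by
ϑ with the global phase fixed; no W⁺ is involved, so the pointwise products
are preserved to machine precision.

## Validation surfaces

The projection test measures coil-map quality without ground truth: coil
images m = F⁻¹y from fully sampled data are projected pointwise onto the
span of the estimated coils, P_c(r) = c(r)c(r)ᴴ/‖c(r)‖², and the RSS of
m − P_c m should contain only noise. Where ‖c(r)‖ = 0 the projector is the
zero map (the continuous limit), keeping the report total. The support mask
is |ρ| > 0 for simulations and an RSS threshold (10% of maximum) for measured
data. `pole_recovery_score` greedily matches detected to true poles within a
tolerance and equal sign, reporting matches/misses/false positives and mean
localization error.

## Synthetic data: what it does and does not emulate

The generator provides piecewise-constant ellipse phantoms with a smooth
low-order polynomial phase (a true image has no phase singularity — its
phase is a single-valued integral of the local field), and two coil
families. `gaussian_ring` places Gaussian magnitude lobes (σ = 0.5 FoV) on a
ring of radius 0.5 with near-linear per-coil phases: receive sensitivity
varies on the scale of the coil-to-FoV distance, so at the grid sizes where
coils are estimated the maps are very smooth and singularity-free. `dipole`
evaluates the transverse field of a point magnetic dipole m·ê_z on an offset
plane, c ∝ B_x − iB_y — an analytic coil with exactly one in-plane phase
singularity and vanishing amplitude there, standing in for the virtual coils
that coil compression can produce (the value at the singular pixel is the
analytic limit 0, phase arbitrarily 0; the winding code treats exact zeros
specially). `plant_artificial_pole` multiplies the image by a vortex and all
coils by its conjugate, realizing the gauge ambiguity exactly without
touching the data.

Not emulated: measurement-correlated noise (pre-whitening is assumed),
non-Cartesian trajectories, off-resonance/field maps, 3D vortex lines, and
actual coil compression. Passing tests therefore demonstrate correctness of
the estimator and the detection/correction logic under the stated model, not
robustness to physical effects outside it.

## Numerical choices and known limitations

* Problem sizes: tests and the acceptance script use 64×64 grids with 8
  coils, 12 Gauss–Newton steps, and 50-run detection ensembles — small
  enough to run on one CPU in seconds while exercising every code path.
* The noiseless full-mask reconstruction converges to a *bias floor* set by
  α_min: at α_min = 0.001 the stationary relative data residual is ≈ 2e-3
  even when the true coils are band-limited to the Sobolev passband, and the
  corresponding coil-direction (projection-test) fraction is ≈ 2e-3; with
  the default ring coils the measured values are ≈ 7e-3 and ≈ 5e-3. Pushing
  below that requires a smaller α_min, not more iterations.
* Winding detection is exact for isolated vortices at loop diameters ≥ 2 px;
  two opposite-sign poles closer than d cancel along the loop and are
  invisible by construction (in the iterative solver such pairs annihilate
  on their own).
* Detection cannot see poles within d/2 of the FoV boundary (clipped loops).
* Thresholding uses strict |S̄| > t.
* Degenerate inputs: all-zero k-space is rejected at normalization; zero
  total coil weight gives S̄ = 0; a zero global-phase inner product leaves
  ϑ unchanged with a warning.
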