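# Methods

This note documents the models, numerical choices and limitations behind
`lowfield-t1map`, in the order the pipeline runs.

## Signal model

Every voxel is modelled as a single T1 compartment following

S(TI) = PD · (1 − (1 + η) e^(−TI/T1) + e^(−TR/T1)),

with TI and TR in ms, PD an arbitrary-unit amplitude, and η ∈ (0, 1] the
inversion efficiency.  η = 1 with TR → ∞ is ideal inversion recovery; the
finite-TR term accounts for incomplete longitudinal recovery between
shots.  The same expression is used by the simulator and the fitter, so
parameter-recovery tests are exact by construction in the noiseless
limit; this is a deliberate closure, and it means those tests validate
the *pipeline* (sampling, reconstruction, phase handling, optimisation),
not the adequacy of the signal model for real tissue.  Echo-train
effects of a turbo-spin-echo readout (T2 blurring along the echo train,
centre-out ordering) are not modelled: each TI is simulated as a
snapshot at its nominal inversion delay, since phantom/tissue T2 values
are not part of the protocol definition and T1 is the target quantity.

Default protocol values: six inversion times log-spaced 50–999 ms
(geometric progression rounded to integer ms: 50/91/166/302/549/999),
TR = 1500 ms, matrix 72×88×58, voxel 2.5×2.5×3.5 mm³, 8 coils, 4×
undersampling.  Tests and examples use reduced desk-scale grids
(48×48×24 or smaller, 4 coils) so the whole suite runs in well under an
hour on one core; nothing in the algorithms depends on matrix size.

## Synthetic data

The phantom generator places spheres with known T1/PD (and optionally
NiCl₂ concentration) on an integer label grid; overlapping spheres are
resolved in favour of the later-listed sphere (documented tie-break).  A
sphere is clipped at the grid boundary; only a centre outside the grid
is rejected.  A smooth low-order polynomial background phase multiplies
all TIs identically, emulating receive-chain and B0-related phase.

Coil sensitivities are Gaussian lobes placed on a ring around the
field of view with coil-specific linear phase ramps, root-sum-of-squares
normalised to 1 everywhere.  This reproduces the two properties the
reconstruction actually relies on — smoothness and RSS normalisation —
but not the physics of coil coupling or load-dependent scaling.

Sampling masks live on the (ky, kz) phase-encode plane (readout kx is
always fully sampled).  Inside an elliptical shutter, points are drawn
without replacement with probability ∝ (1 − r)² + 0.05, r the
normalised elliptical radius, so the density decays towards the k-space
edge; exactly ⌊n_shutter/R⌉ points are kept per TI, giving a realised
density of 1/R up to rounding.  The central 4×4 block is always sampled
to support coil-map autocalibration; masks are drawn independently per
TI.  Noise is i.i.d. circular complex Gaussian added at sampled
locations only; `sigma` is the complex SD (per-component SD = σ/√2).
Because the FFT convention is orthonormal, a k-space σ maps to the same
image-domain noise SD, so SNR ≈ peak image magnitude / σ.

What the simulator does **not** emulate: EMI, B0/gradient imperfections,
motion, T2 decay, partial-volume mixtures, and realistic anatomy.
Passing recovery tests therefore demonstrate the numerical correctness
and noise robustness of the chain, not in vivo accuracy.

## Reconstruction

The joint problem

argmin_x Σ_n ‖D_n F S x_n − y_n‖₂² + λ Σ_b ‖R_b{x_1..N}‖_*

is solved by ADMM with the splitting z = x:

1. x-update: per TI, (AᴴA + ρ/2) x = Aᴴy + (ρ/2)(z − u) by conjugate
   gradients (10 iterations or relative residual 1e−6, warm-started);
2. z-update: blockwise SVT with threshold τ = λ/ρ on x + u;
3. dual update u ← u + x − z.

Blocks are 8×8×8, non-overlapping with cyclic wrap (edge blocks shrink
when a dimension is not divisible), and a random cyclic shift of the
tiling is redrawn each iteration (seeded) to suppress block-boundary
artefacts while keeping each per-iteration prox exact.  Default 20
iterations, ρ = 1 in normalised units (k-space scaled to max |y| = 1
and rescaled afterwards).  λ defaults to 1% of the largest blockwise
Casorati singular value of the zero-filled reconstruction — a
scale-invariant heuristic exposed as a configuration knob.  The
objective is evaluated at every x-iterate and reported in the
diagnostics; on noiseless problems it decreases overall, with the
bounded oscillation typical of ADMM.

Numerical caveat: with λ = 0 the scheme degenerates to a proximal-point
recursion whose convergence rate in the weak eigendirections of AᴴA is
(ρ/2)/(μ + ρ/2); at finite iteration counts the output agrees with a
direct CG SENSE solve up to semi-convergence in those directions.  The
tests assert data-consistency and high image correlation rather than
bitwise equality for this reason.

Coil maps are autocalibrated from the last-TI k-space (the TI with the
strongest signal): the guaranteed-sampled central (ky, kz) block is Hann
apodised (together with a width-16 Hann along the fully sampled
readout), inverse transformed per coil, and divided by the
root-sum-of-squares image; voxels with RSS below 5% of the maximum are
outside the support and zeroed.  This is a deliberately simple
autocalibration, adequate for smooth sensitivities; because the same
maps multiply every TI, a static map error rescales PD locally but
leaves T1 untouched.

## Fitting

Phase correction multiplies each TI by exp(−i·arg x_last) and keeps the
real part; the last TI becomes its own magnitude.  Voxels with zero
last-TI magnitude have no reference; they fall back to the
sign-of-real-part magnitude series and are flagged out of `fit_mask`.

The default fit fixes η = 1, leaving (PD, T1).  PD enters linearly, so
it is profiled out in closed form and the problem reduces to a 1D search
over T1: a coarse grid (50–1500 ms in 50 ms steps, plus the bounds)
followed by bounded Brent refinement between the neighbouring grid
points (xatol 1e−4 ms).  The grid initialisation avoids the local minima
that the null-point sign flip creates for gradient-started solvers.  An
optional 3-parameter mode frees η ∈ (0, 1] via bounded
Levenberg–Marquardt started from the 2-parameter solution.  T1 bounds
default to [10, 5000] ms; fits terminating within 0.1% of a bound are
flagged `at_bound` and excluded from `fit_mask`, hence from all ROI
statistics downstream.  RMSE = √(SSE/N) over the TI samples.  The TI
schedule is optimised for 100–1000 ms: recovery outside that range
(e.g. CSF-like T1 ≈ 4000 ms) is strongly biased at realistic SNR, which
the tests assert as a property rather than treat as a defect.

## Statistics

All standard deviations use the sample (n−1) denominator.  CV =
100·SD/mean (%); RC = 1.96·√2·SD (ms); Bland–Altman limits of agreement
at mean difference ± 1.96 SD of the paired differences.  The relaxivity
fit regresses R1 = 1000/T1[ms] (s⁻¹) on concentration (mM) by ordinary
least squares, using only points with T1 inside the optimised
[100, 1000] ms window.  ANOVA, Tukey HSD (studentized range;
Tukey–Kramer for unequal n), and paired t-tests are delegated to
scipy.stats behind the module interface; degenerate inputs
(zero-variance differences, all-identical groups) return flagged
results instead of raising.  Histograms use 200 bins over 1–500 ms;
FWHM is measured between the outermost half-maximum crossings with
linear interpolation between bin centres (flagged when noise produces
multiple crossing pairs) and reported in seconds; skewness is the
Fisher–Pearson g1 of the raw values.  Report rounding follows the
study convention: CV to 2 decimals, RC and T1 to 1 decimal.

## Design choices made where the design was open

- Block size, overlap, λ, ρ and CG tolerances for the LLR solver are not
  protocol constants; the defaults above are standard LLR practice and
  are all exposed in `LLRConfig`.  Consequently only statistical — not
  bitwise — agreement with any particular scanner implementation is
  expected.
- Whether the product sequence reuses one sampling mask across TIs is
  unspecified; independent per-TI masks are assumed (they improve the
  conditioning of the joint problem).
- The fitter offers both 2- and 3-parameter modes because the number of
  free parameters per voxel in deployed fitting tools varies; the
  2-parameter mode is the default as the stabler choice at six TIs.
- NIfTI outputs use an RAS+ diagonal affine from the voxel size; complex
  series are stored as real/imaginary pairs because NIfTI complex
  support is inconsistent across readers.

## Known limitations

- The coil autocalibration degrades if sensitivities vary faster than
  the central-block resolution; it is not a substitute for model-based
  calibration on real data.
- The ADMM solver is plain single-threaded numpy/scipy; large matrices
  (full 72×88×58, 8 coils) take tens of minutes per reconstruction.
- Repeatability metrics operate on ROI session means supplied as
  tables; the package does not segment anatomy.
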