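# lowfield-t1map

Quantitative T1 mapping for undersampled multi-inversion-time MRI, built
for the very-low-field (tens of mT) regime where long acquisition times
and low SNR make accelerated acquisition and regularised reconstruction
mandatory.  The package covers the full measurement chain as testable
code: simulation of multi-coil inversion-recovery k-space from digital
phantoms, joint locally-low-rank (LLR) reconstruction of all inversion
times with an ADMM solver, phase-corrected voxelwise T1 fitting, and the
repeatability/reproducibility statistics used to validate such protocols
(coefficient of variation, repeatability coefficient, Bland–Altman
agreement, relaxivity fits, ANOVA with Tukey HSD, histogram shape).

It is aimed at MR physicists and image-analysis researchers who want to
prototype or validate T1-mapping protocols without scanner access: every
stage runs on synthetic data with known ground truth.

## The model

The acquisition collects undersampled k-space `y_n` at N inversion times
TI_n.  All TIs are reconstructed jointly by solving

```
{x_1..N} = argmin  Σ_n ‖ D_n F S x_n − y_n ‖₂²  +  λ Σ_b ‖ R_b{x_1..N} ‖_*
```

where `S` are coil sensitivities, `F` the orthonormal 3D DFT, `D_n` the
per-TI variable-density sampling mask (elliptical k-space shutter, fully
sampled readout), and `R_b` extracts a small 3D block, vectorises it per
TI and stacks the columns into a Casorati matrix.  Because every voxel
relaxes on a shared exponential manifold, these matrices are nearly low
rank; the nuclear norm `‖·‖_*` (L1 of the singular values) penalises
undersampling artefacts that break that structure.  An ADMM solver
alternates a conjugate-gradient SENSE data-consistency update with
blockwise singular-value soft-thresholding (20 iterations by default).

After referencing every TI to the phase of the last (fully recovered)
image and keeping the real part, each voxel is fit to the
inversion-recovery signal model

```
S(TI) = PD · (1 − (1 + η) e^(−TI/T1) + e^(−TR/T1))
```

yielding T1 (ms), proton density PD (a.u.) and the RMSE of the fit.  The
statistics layer then summarises repeated measurements: CV = 100·SD/mean,
RC = 1.96·√2·SD, Bland–Altman limits of agreement at ±1.96 SD, and the
NiCl₂ relaxivity line R1 = r1·C + R1(C=0) fit over the protocol's
optimised 100–1000 ms range.

## Worked example

Simulate a 4×-undersampled, 4-coil scan of a two-sphere phantom at
SNR ≈ 20, reconstruct, fit, and summarise:

```python
import numpy as np

from t1map import (AcquisitionSpec, FitConfig, LLRConfig, add_noise, admm_llr,
                   estimate_coil_maps, fit_t1_map, forward_model,
                   make_sampling_mask, make_sphere_phantom,
                   make_synthetic_coil_maps, phase_correct, roi_stats,
                   simulate_image_series)

spec = AcquisitionSpec(matrix_dims=(48, 48, 24), n_coils=4,
                       undersampling_factor=4.0)
phantom = make_sphere_phantom(
    spec.matrix_dims,
    [((16.0, 24.0, 11.5), 7.0, 252.8, 1.0, None),   # white-matter mimic
     ((32.0, 24.0, 11.5), 7.0, 354.4, 0.9, None)])  # cortex mimic
images = simulate_image_series(phantom, spec)
coils = make_synthetic_coil_maps(spec.n_coils, spec.matrix_dims, seed=7)
mask = make_sampling_mask(spec, seed=7)
ksp = add_noise(forward_model(images, coils, mask),
                sigma=np.abs(images.data).max() / 20.0, seed=8)   # SNR ~ 20

maps = estimate_coil_maps(ksp)
recon, diag = admm_llr(ksp, maps, LLRConfig(n_iter=20, block_size=8, seed=7))
quant = fit_t1_map(phase_correct(recon), phantom.label_volume > 0, spec,
                   FitConfig())
for roi in roi_stats(quant, phantom.label_volume):
    truth = phantom.t1[roi.roi_label]
    print(f"sphere {roi.roi_label}: T1 = {roi.mean_t1:6.1f} +/- {roi.sd_t1:4.1f} ms "
          f"(truth {truth}, n = {roi.n_voxels})")
print(f"objective: {diag['objective'][0]:.2f} -> {diag['objective'][-1]:.2f} "
      f"over {diag['n_iter']} ADMM iterations")
```

Output (about half a minute on one core):

```
sphere 1: T1 =  253.4 +/-  5.2 ms (truth 252.8, n = 1422)
sphere 2: T1 =  354.0 +/-  8.1 ms (truth 354.4, n = 1422)
objective: 27.06 -> 25.10 over 20 ADMM iterations
```

Despite 4× undersampling and noise, the sphere means land within a
fraction of a percent of the ground truth; the per-voxel SD reflects the
noise floor of the protocol.  The same pipeline is scriptable from the
shell (`t1map simulate | recon | fit | stats`, each with `--config`,
`--seed`, `--out`).

The repeatability layer works directly on session summaries.  Six
repeated measurements of a structure with mean 252.8 ms and temporal SD
1.9 ms give:

```python
>>> from t1map import compute_cv, compute_rc
>>> round(compute_cv(252.8, 1.9), 2), round(compute_rc(1.9), 1)
(0.75, 5.3)
```

i.e. a CV of 0.75 % and a repeatability coefficient of 5.3 ms — the
largest test–retest change expected 95 % of the time.

## Layout

- `src/t1map/synthkspace.py` — digital phantoms, coil maps, sampling
  masks, the acquisition forward model and its adjoint, noise.
- `src/t1map/llr_recon.py` — Casorati blocking, SVT, coil-map
  autocalibration, the ADMM solver.
- `src/t1map/t1fit.py` — phase correction and voxelwise IR fitting.
- `src/t1map/quantstats.py` — CV/RC, Bland–Altman, relaxivity,
  ANOVA/Tukey, paired tests, histogram shape, ROI tables.
- `src/t1map/cli.py` — the `t1map` command.
- `docs/methods.md` — modelling assumptions, parameter choices and
  limitations.
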