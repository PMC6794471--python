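# Methods

## Signal model and pipeline

Each of the M_c input contrasts is a complex-valued 3D image observed as a
magnitude volume A(x) ≥ 0 and a phase volume φ(x) ∈ [−π, π). The noise
model is additive complex Gaussian: independent N(0, σ²) perturbations on
the real and imaginary parts, which makes observed magnitudes Rician. The
pipeline runs in five stages:

1. **Phase unwrapping.** φ is unwrapped by quality-guided region growing:
   starting from the highest-magnitude voxel, the solved region grows one
   voxel at a time through a priority queue keyed on the quality
   (magnitude) of the candidate voxel; each new voxel is unwrapped against
   the neighbour that enqueued it by adding the 2π multiple that minimises
   the jump. High-SNR voxels are therefore solved before noise-dominated
   ones and wrap errors cannot propagate inward from dark regions. The
   result is anchored so the median added 2π multiple is zero. The
   algorithm is deterministic (ties broken by insertion order).

2. **Global/residual phase split.** The unwrapped phase is decomposed as
   φ_u = φ_global + φ_residual, where φ_global minimises the ROF
   functional ½‖u − φ_u‖² + λ·TV(u) (isotropic TV, forward differences,
   Neumann boundaries), solved by Chambolle's dual projection iteration
   with step τ = 1/(4·ndim), at most 500 iterations, stopping when the
   relative change of u falls below 1e−5. The residual is the exact
   difference, so the additive decomposition holds to float precision.
   Each contrast is processed independently: different echoes and
   inversions see different global fields.

3. **Complex reconstruction.** real_c = A_c·cos(φ_residual,c),
   imag_c = A_c·sin(φ_residual,c), stacked as M = 2·M_c channels. Both
   channels inherit the Gaussian noise of the complex signal — the reason
   for working in the complex domain rather than on Rician magnitudes.
   Voxels with zero magnitude have undefined phase; their residual is set
   to 0 and they carry no weight in the unwrapping.

4. **Local PCA with the linear-fit noise threshold.** Overlapping N³
   patches (origins on a stride grid, boundary origins clamped inside the
   volume) are unfolded to N³×M matrices, column-centered and decomposed
   by SVD. A least-squares line through the fit_count = ⌊M/2⌋ smallest
   singular values (abscissa: rank index in the descending spectrum)
   estimates the noise floor; rank i is kept iff s_i > (1+α)·line(i) with
   the line clamped at 0. Retained components form a prefix of the
   spectrum — the first failing rank truncates — because the
   reconstruction projects onto a leading subspace and isolated deeper
   exceedances are noise. Patches are rebuilt from the kept subspace plus
   their means, and overlapping estimates averaged with weights
   W = 1/(1 + M_kept) (normalised by ΣW). The kept-count and the line's R²
   are averaged the same way into two QC maps. R² is defined as 1 when the
   fitted values are constant and exactly fitted (perfect-fit semantics
   for the QC map).

5. **Restoration.** Magnitude and phase are recovered per contrast
   (hypot / atan2), the global phase re-added, and phases wrapped back to
   [−π, π). With the thresholding disabled the whole pipeline is the
   identity on magnitude, and on phase modulo 2π wherever magnitude > 0.

## The Marchenko–Pastur comparison threshold

For i.i.d. Gaussian noise the covariance eigenvalues λ_i = s_i²/N³ of a
pure-noise patch fall in the MP bulk of width 4σ²√γ, γ = M/N³. Scanning
p = 0, 1, … signal components, the M−p smallest eigenvalues are accepted
as noise as soon as their empirical spread (largest − smallest) is below
the bulk width implied by their own mean; the smallest such p is the
component count. This estimator is exact in spirit for large matrices but
fragile at M = 10, and it assumes homoscedastic uncorrelated noise — the
assumption that interpolation breaks.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| patch_size N | 4 | patch edge (voxels); 64 samples against 10 variables |
| alpha α | 0.05 | relative margin above the fitted noise line |
| stride | 2 | N/2: 8-fold interior coverage; 1 gives fully overcomplete sweeps |
| fit_count | ⌊M/2⌋ | noise-line support; requires intrinsic dimension < M/2 |
| tv_weight λ | 4.0 | ROF weight of the global-phase split (see below) |

λ is calibrated on the phantom, not taken from any reference: it is chosen
so that (a) smooth phase structure with wavelength ≳ 20 voxels stays in
the global component (interior residual of a multi-radian ramp < 0.05
rad), (b) voxel-scale phase features land in the residual (> 90% of a
localised bump's energy), and (c) the TV smoothing absorbs less than 10%
of the phase-noise standard deviation into the global estimate, so the
reconstructed channels keep the full complex noise. Larger weights start
leaking ramp structure into the residual; smaller ones absorb noise into
the global phase.

## Synthetic data

`generate_phantom` emulates a subcortical quantitative-MRI slab: a tissue
background plus a nucleus-like sphere, a box, and two vessel-like tubes of
radius 1 and 2 voxels, each with its own per-contrast intensity profile
(values around 100 signal units with a mild monotone trend across
contrasts, mimicking echo-dependent decay). The default noise σ = 10 per
real/imaginary channel puts tissue at SNR ≈ 10. The global phase is a
low-order 3D polynomial per contrast whose amplitude grows with contrast
index and spans several cycles, so the stored phase wraps. Structure
positions scale with the grid; tube radii stay absolute because vessel
thinness is the point. The phantom does **not** model coil sensitivities,
B1/B0 physics, partial-volume ramps, spatially varying noise, or motion —
so passing tests demonstrate correct statistical behaviour under the ideal
complex-Gaussian model, not performance on scanner data.

`simulate_patch` builds one N³×M patch: a rank-k signal Σ u_k v_kᵀ with
random orthonormal spatial and contrast factors and equal (unit) component
amplitudes, plus i.i.d. Gaussian noise with σ = RMS(signal)/SNR — an
RMS-based SNR definition, scale-free and symmetric across components. The
equal-amplitude choice makes "ideal kept = rank" well-posed. In the
interpolated regimes the *noise* is drawn on an (N+2)³ support, resampled
trilinearly on a grid shifted by a uniform random offset of up to half a
voxel per axis (one shared shift, or an independent shift per dimension),
and cropped to the interior N³ block so no extrapolation occurs.
Interpolation is applied to the noise component only: resampling each
dimension with a different operator would also distort the signal factors
and inflate the true signal rank beyond the nominal k (random orthonormal
spatial patterns are white-noise-like and far more sensitive to resampling
than smooth anatomy), which would confound the quantity under study — the
threshold's response to *correlated noise* at a known, fixed signal rank.
With this construction the planted rank remains the ideal kept-count in
every regime; under per-dimension interpolation the linear-fit median
moves from 3 to 4 while the MP threshold's distribution shifts strongly
upward (mean ≈ 3.1 → 4.7).

## Numerical choices and degenerate inputs

- Threshold semantics are multiplicative (s > (1+α)·line); an additive
  margin would be scale-dependent across contrasts.
- The noise line is evaluated at each singular value's own rank when
  thresholding ranks above the fitted range.
- Negative line predictions clamp to 0 (singular values are nonnegative),
  so any strictly positive singular value passes where the line is 0.
- Patches with fewer voxels than channels zero-pad the spectrum; all
  volumes processed here satisfy N³ ≥ M.
- Boundary patches are clamped, not zero-padded: padding would inject
  artificial edges into the PCA.
- SVD, eigendecompositions and the OLS fits use closed-form linear algebra
  (LAPACK via numpy); the QR used for random orthonormal factors fixes
  signs from the R diagonal so results do not depend on the BLAS build.
- Region SNR uses the population (1/n) standard deviation; at the region
  sizes used the n vs n−1 choice moves SNR by < 0.1%. Uniform regions
  report SNR as NaN (undefined), never infinity.
- T2* fitting flags voxels with any nonpositive echo or a nonpositive
  fitted decay rate as invalid (NaN in the maps) rather than extrapolating.
- Phase volumes whose value range is not radians are linearly rescaled
  from a documented list of conventions ([0, 2π), degrees, ±4096 integer
  scaling) with the rescaling logged; anything else fails loudly rather
  than silently corrupting the complex reconstruction.
- NIfTI outputs are written uncompressed so repeated runs are
  byte-identical (gzip embeds timestamps); gzipped inputs are accepted.

## Problem sizes

The validation suite uses 10,000 repetitions for the patch-threshold
experiments (the full study size), a 64³ five-contrast phantom for the
end-to-end efficacy and edge-preservation checks, and 16³–32³ phantoms for
identity and bias properties. These sizes were chosen so the whole suite
documents the method at full statistical fidelity while remaining quick to
run on a single CPU.

## Known limitations

- The ROF model flattens even a perfectly smooth ramp near the volume
  faces (Neumann boundary shrinkage of ~0.3–0.8 rad at typical weights);
  the corresponding structure moves into the residual phase there. This is
  harmless for denoising — the residual stays smooth and low-amplitude —
  but the global-phase map should not be interpreted as a field map near
  the faces.
- Quality-guided unwrapping is robust at the SNRs tested (< 1% wrap errors
  at SNR 10 on a 3-cycle ramp) but, like all path-following methods, can
  propagate errors across closed low-quality surfaces that disconnect
  high-quality regions.
- The linear noise-floor approximation relies on M being small; for
  M ≫ 20 the MP bulk's curvature makes a straight line a poor model and
  the random-matrix threshold becomes preferable.
- The intrinsic signal dimension must stay below ⌊M/2⌋ or the fitted line
  is contaminated by signal.
- T1 lookup-table mapping and quantitative susceptibility mapping are out
  of scope; the pipeline emits the denoised complex images those external
  tools consume.
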