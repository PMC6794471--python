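# lcpca — local complex PCA denoising for multi-contrast MRI

Quantitative MRI sequences such as MP2RAGEME acquire several co-registered
complex-valued images (inversions and echoes) in one scan. Their anatomy is
highly redundant across contrasts, while the thermal noise is independent —
exactly the situation where patch-based PCA can separate signal from noise.
Two obstacles stand in the way of applying the classical local-PCA recipe
from diffusion MRI: magnitude images carry Rician (not Gaussian) noise,
which biases low-SNR regions, and with only M ≈ 10 images the usual
random-matrix noise thresholds become fragile, especially after the spatial
interpolation introduced by registration or motion correction.

`lcpca` addresses both. It works on the complex signal — magnitude combined
with the *residual* phase after unwrapping and removing the smooth global
phase by total-variation smoothing — so every channel carries plain
Gaussian noise. Each overlapping N×N×N patch is unfolded into an N³×M
matrix (contrasts as variables), column-centered and decomposed by SVD:

    X_c = U S Vᵀ,   s₁ ≥ s₂ ≥ … ≥ s_M

A straight line is fitted by least squares to the ⌊M/2⌋ smallest singular
values — the noise floor, which is close to linear when M is small — and a
component at rank i is retained iff

    s_i > (1 + α) · line(i),   α = 0.05 by default.

The patch is rebuilt from the retained subspace and overlapping estimates
are averaged with weights W = 1/(1 + M_kept), favouring sparse local
descriptions. Patch-weighted maps of M_kept and of the noise-line R² are
produced for quality control, and the global phase is reintroduced at the
end so outputs look like the inputs. A Marchenko–Pastur threshold is
included as the random-matrix comparison method, together with a synthetic
phantom generator, the patch-level threshold simulation used to validate
the estimators, and downstream T2* (log-domain fit) and region-SNR metrics.

Intended users: researchers processing multi-echo / multi-inversion
structural MRI who need denoising that preserves thin structures (vessels,
small nuclei) and stays unbiased at low SNR.

## Worked example

Validate the noise threshold on simulated patches (4×4×4 voxels, 10
dimensions, 3 signal components, SNR 20):

```sh
lcpca simulate --rank 3 --snr 20 --reps 10000 --seed 7
```

```
    method  median_kept  mean_kept  kept_0  kept_1  kept_2  kept_3  kept_4  kept_5  kept_6 ...
linear_fit          3.0     3.4772       0       0       0    6510    2225    1248      17 ...
       rmt          3.0     3.0750       0       0       0    9310     637      47       5 ...
```

Both estimators find the planted rank 3 in the median; the histograms show
how often extra noise components slip through. With
`--interpolation per_dimension` the noise becomes spatially correlated and
the Marchenko–Pastur counts inflate strongly while the linear fit moves by
about one component.

Denoising a synthetic five-contrast phantom (32³, complex noise at SNR ≈ 10
on tissue) and scoring the per-structure SNR gain:

```python
from lcpca import (PhantomSpec, generate_phantom, denoise_complex_images,
                   snr_improvement)

truth, noisy, labels = generate_phantom(PhantomSpec(shape=(32, 32, 32), seed=1))
result = denoise_complex_images(noisy)
names = {1: "sphere", 2: "box", 3: "tube_r1", 4: "tube_r2"}
print(snr_improvement(noisy.magnitudes[0], result.images.magnitudes[0],
                      labels, names))
```

```
{'sphere': 7.72, 'box': 14.83, 'tube_r1': 17.00, 'tube_r2': 17.19}
```

SNR (mean/std inside each structure mask) improves in every structure,
including the radius-1-voxel tube — thin bright structures are preserved,
not blurred away. `result.dimension_map` and `result.fit_map` are the QC
volumes; on this phantom the mean local dimension is 1.38.

The same pipeline runs on real NIfTI data from the shell:

```sh
lcpca denoise -m inv1_mag.nii -p inv1_phs.nii -m echo1_mag.nii -p echo1_phs.nii \
      -o denoised/        # patch size 4, alpha 0.05, stride 2 by default
```

writing one magnitude + one phase volume per contrast, the two QC maps and
a JSON run log with all resolved parameters and stage timings.

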