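# fanlm

Adaptive non-local-means denoising of Rician-noise magnitude MR brain
images, with automatic noise-level estimation and fast robust fuzzy c-means
(FRFCM) segmentation.

## The problem

Magnitude MR images carry **Rician** noise: complex k-space data with
Gaussian noise in both channels is magnitude-reconstructed, so intensities
follow a Rice distribution — Rayleigh in air, approximately Gaussian in
bright tissue.  Most denoisers assume Gaussian noise and a fixed filter
configuration.  This package implements a pipeline for single 2D slices
(or 3D volumes slice-by-slice) aimed at radiology/neuroimaging pipelines
that need denoised, optionally segmented T1-like brain slices:

1. **Noise estimation.**  The diagonal (HH) sub-band of a single-level
   wavelet transform is noise-dominated, giving the robust estimate
   σ̂ = median(|HH|)/0.6745.  Because the magnitude operation suppresses
   apparent noise at low SNR, σ̂ is corrected through the analytic factor

   ζ(θ) = 2 + θ² − (π/8) e^{−θ²/2} [(2+θ²) I₀(θ²/4) + θ² I₁(θ²/4)]²,

   where θ is the SNR obtained from the fixed point
   θ ← sqrt(ζ(θ)(1 + m̄₀²/σ̂²) − 2) (m̄₀ = mean signal, convergence at
   |Δθ| ≤ 10⁻⁸), yielding σ_n² = ζ(θ)·σ̂².
2. **Non-local means at three window sizes.**  Classic NLM
   û(i) = Σ_{j∈S_i} w(i,j) v(j), w(i,j) ∝ exp(−‖p(N_i)−p(N_j)‖²_{2,a}/h²),
   run with search windows 7×7, 13×13 and 21×21 (h = 1.2·σ_n, 5×5 patches).
3. **Per-pixel window selection.**  For each window size c the estimated
   signal variance σ̂²_{g,c} = max(σ²_{f,c} − σ_n², 0) of the noisy input is
   compared with the local variance of the c-filtered image; each pixel
   takes its value from the filtered image minimising
   |σ̂²_{g,c} − σ̂²_{NLM,c}|.
4. **FRFCM segmentation** (optional): morphological-reconstruction
   smoothing, fuzzy c-means on the gray-level histogram, and median
   filtering of the membership maps, giving tissue labels and fuzzy
   memberships.

A synthetic brain-phantom generator with ground-truth labels and an exact
Rician noise model makes every stage testable without external data.

## Worked example

```python
import numpy as np
from fanlm import (brain_phantom_spec, make_phantom, add_rician_noise_percent,
                   fanlm_denoise, frfcm_segment, FRFCMParams, psnr, ssim)

phantom = make_phantom(brain_phantom_spec(128, 128))
noisy, sigma = add_rician_noise_percent(phantom.image, 9.0, seed=1)

result = fanlm_denoise(noisy)
est = result.noise_estimate
print(f"true sigma      {sigma:.4f}")
print(f"estimated sigma {est.sigma_n:.4f}  (theta={est.theta:.2f}, zeta={est.zeta_value:.4f})")
print(f"PSNR noisy    {psnr(phantom.image, noisy):.2f} dB   SSIM {ssim(phantom.image, noisy):.3f}")
print(f"PSNR denoised {psnr(phantom.image, result.denoised):.2f} dB   SSIM {ssim(phantom.image, result.denoised):.3f}")

labels, mm = frfcm_segment(result.denoised, FRFCMParams(n_clusters=4))
print("cluster centers", np.round(mm.centers, 3))
```

Output:

```
true sigma      0.0720
estimated sigma 0.0695  (theta=5.40, zeta=0.9822)
PSNR noisy    21.25 dB   SSIM 0.397
PSNR denoised 29.12 dB   SSIM 0.842
cluster centers [0.13  0.253 0.555 0.793]
```

The phantom's peak intensity is 0.8, so 9% noise means σ = 0.072; the
estimator recovers it within 3.5%.  Denoising raises PSNR by ~8 dB and more
than doubles SSIM, and the four cluster centres land on the background
floor, CSF-dark rim, grey-matter and white-matter intensities
(0.10/0.25/0.55/0.80 in the phantom).

## Command line

```bash
fanlm phantom --size 256 256 --noise-level 9 --seed 1 \
      --out clean.nii.gz --out-noisy noisy.nii.gz
fanlm estimate-noise noisy.nii.gz --as-json
fanlm denoise noisy.nii.gz denoised.nii.gz --save-choice-map choice.nii.gz
fanlm denoise noisy.nii.gz nlm.nii.gz --method nlm --window 13
fanlm segment denoised.nii.gz labels.nii.gz --clusters 4
fanlm evaluate --ref clean.nii.gz --test denoised.nii.gz
```

Formats: NIfTI-1 (`.nii`/`.nii.gz`), PNG, TIFF.  Exit codes: 0 ok, 1 user
error, 2 internal error.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults and
their rationale, numerical conventions (boundary handling, tie-breaking,
degenerate inputs), what the phantom generator does and does not emulate,
and known limitations.
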