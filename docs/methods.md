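# Methods

## Noise model and the synthetic phantom

Magnitude MR noise is modelled exactly as magnitude reconstruction of a
complex signal with i.i.d. Gaussian noise in both channels:
v = sqrt((u + n₁)² + n₂²), n₁, n₂ ~ N(0, σ²).  This is Rician with
parameter u/σ — Rayleigh where u = 0 and asymptotically N(u, σ²) at high
SNR.  Percent noise levels follow the BrainWeb convention relative to the
brightest tissue: p% means σ = (p/100)·max(u).  The generator uses numpy's
default PCG64 generator seeded explicitly, so outputs are bit-reproducible
across runs and platforms.

The default brain phantom (`brain_phantom_spec`) is a stack of rotated
ellipses on a 0.10 background floor: a CSF-dark rim (0.25), grey-matter
shell (0.55), white-matter core (0.80, the brightest tissue) and two dark
ventricles, the head filling roughly 58% of the frame.  The background
floor is deliberately non-zero: real T1 slices are mostly tissue with a
limited air fraction, and a frame dominated by pure-Rayleigh background
would make the wavelet-MAD median measure the magnitude-suppressed
background fluctuation rather than the tissue-level noise.  An optional
Gaussian blur of the intensity image (``smoothing_sigma``) softens tissue
edges; the label map stays crisp.

What the phantom does **not** emulate: 3D anatomy, partial-volume mixtures,
bias fields, motion/ghosting, k-space sampling, or spatially varying
(parallel-imaging) noise.  Tests passing on phantoms therefore demonstrate
the pipeline's correctness and its behaviour under the stated noise model,
not clinical performance.

## Noise estimation

* Wavelet basis: Haar, single level (configurable).  PyWavelets' symmetric
  boundary extension; an H×W image yields a ceil(H/2)×ceil(W/2) HH grid.
  For Haar the HH coefficient of a 2×2 block [[a,b],[c,d]] is (a−b−c+d)/2,
  so i.i.d. noise of std σ gives HH coefficients of std σ and
  median(|HH|)/0.6745 is unbiased for Gaussian noise.
* The correction factor ζ(θ) is evaluated with exponentially scaled Bessel
  functions (`scipy.special.ive`); the e^{−θ²/2} prefactor cancels
  analytically, so ζ is overflow-free for any θ and satisfies
  ζ(0) = 2 − π/2 and ζ → 1 monotonically.
* SNR fixed point: θ ← sqrt(ζ(θ)(1 + m̄₀²/σ̂²) − 2), initialised at the
  naive SNR m̄₀/σ̂, ε = 10⁻⁸, max 500 iterations.  The ratio enters
  **squared** (m̄₀²/σ̂²) so the radicand is dimensionless.  A negative
  radicand (signal ratio below the pure-noise floor sqrt(π/2)) clamps θ to
  0; the next iterate is again 0, so the pure-noise regime converges
  rather than erroring.  m̄₀ is the whole-image mean by default; an Otsu
  foreground mask is available for images with large air backgrounds.
* σ_n² = ζ(θ)·σ̂² ("multiply").  A "divide" convention
  (σ_n² = σ̂²/ζ(θ)) is provided for users who read σ̂ as the
  SNR-suppressed magnitude fluctuation and want the underlying channel σ;
  at tissue-level SNR the two differ by under 2%.
* Degenerate inputs: a constant (noise-free) image returns σ_n² = 0
  directly; `estimate_snr` itself raises on σ̂ = 0 since θ is undefined.

## Non-local means

* Patch: 5×5 (radius 2), weighted by a normalised isotropic Gaussian
  kernel of std a = 1 pixel; the patch distance is the kernel-weighted
  squared L2 difference, so it is a per-pixel-scale quantity and zero iff
  patches are identical.
* Bandwidth: h = 1.2·σ_n by default (h_factor configurable).  With the
  normalised kernel the expected distance between two pure-noise patches is
  2σ², so exp(−d/h²) ≈ 0.25 for matching flat patches while a structural
  difference Δ costs a further factor exp(−Δ²/h²).
* Boundaries: patches read from a whole-sample mirror (numpy ``reflect``)
  padding; the search window is clipped at the image boundary (only
  in-image positions contribute).  Local-variance maps use scipy's
  edge-repeating mirror padding; the two conventions are each documented
  where used.
* Self-weight: w(i,i) = max of the other window weights before
  normalisation (prevents the exact self-match from dominating);
  the literal exp(0) = 1 rule is switchable.
* Implementation: exact sliding-window evaluation — for every window
  offset the squared-difference image is filtered with the separable patch
  kernel, which is numerically identical (verified to 10⁻¹⁵ in tests) to
  the per-pixel double loop over the weight equations.  The weighted
  average is accumulated in difference form, v(i) + Σw·(v(j)−v(i))/Σw, so
  constant images are bitwise fixed points.
* A window side above 2·max(H,W)−1 is rejected: a window of that size
  already reaches every pixel from any centre.

## Window selection and composition

For c ∈ {7, 13, 21}: σ̂²_{g,c} = max(var_c(noisy) − σ_n², 0) against
σ̂²_{NLM,c} = var_c(filtered_c), both per-pixel population variances over a
c×c neighbourhood; the per-pixel argmin of |σ̂²_{g,c} − σ̂²_{NLM,c}| picks
the window, exact ties resolving to the smallest (cheapest,
most detail-preserving).  The output copies each pixel verbatim from its
chosen filtered image, so the composition is bitwise exact.  h and the
patch are shared across the three passes so the criterion compares window
size only, and σ_n² is estimated once from the noisy input.

An alternative "global" mode replaces the per-pixel variances with one
image-wide criterion per window (global signal variance of the input vs
the wavelet-MAD variance of each filtered image), giving a single window
choice for the whole image.  In practice the per-pixel (local) mode is the
default and the global mode is a diagnostic.

**Known limitation.**  The local-variance criterion is noise-limited: in
homogeneous regions the variance estimates over a 7×7 window fluctuate by
~20% and the residual noise of a filtered image is correlated with the
input noise, so the per-pixel choice is only weakly informative there.  On
piecewise-constant phantoms the adaptive composition improves PSNR over
the noisy input by 7–8 dB at 9% noise and is monotone in noise level, but
its median PSNR sits ~0.04 dB below a fixed 13×13 NLM with the same h and
patch; a per-pixel oracle choice (argmin of true error) would gain ~1 dB,
indicating the headroom lies in the selection rule, not the filters.

## FRFCM segmentation

* Reconstruction smoothing: opening-by-reconstruction then
  closing-by-reconstruction with a disk of radius 3; idempotent and
  range-preserving (scikit-image primitives).
* Histogram: 256 bins over the reconstructed range; clustering runs on bin
  centres weighted by pixel counts, making the iteration cost independent
  of image size.  On images with few distinct levels this is exactly
  pixel-wise FCM (verified to 10⁻⁶ against a direct implementation).
* Updates: standard closed forms with fuzzifier m = 2; each level's term
  weighted by its count; the count-weighted objective is non-increasing
  (asserted in tests).  Convergence when the largest centre change drops
  below 10⁻⁵, max 100 iterations.
* Initialisation: centres at evenly spaced quantiles of the weighted
  histogram (deterministic); seeded random initialisation optional.
  A gray level exactly at a centre receives crisp membership (the
  zero-distance singularity of the update rule).
* Membership filtering: 3×3 median per cluster then per-pixel
  renormalisation; an all-zero pixel (impossible after median of
  normalised maps, but guarded) falls back to uniform 1/C.
* Labels are argmax memberships; centres (and membership columns) are
  sorted ascending so label k always means the k-th darkest class.
* Pipeline placement: segmentation runs on the denoised image by default
  (`--fcm post`); `--fcm first` segments the noisy input instead.  The
  denoised image itself is always the adaptive-NLM composition —
  memberships are a product, not a feedback into the filter weights.
* Defaults C = 4 (background/CSF/GM/WM for T1), configurable.

## Metrics

PSNR = 10·log10(range²/MSE) dB with an `inf` sentinel at zero MSE; SSIM is
the standard Gaussian-window (11 taps, σ 1.5) mean local similarity with
K₁ = 0.01, K₂ = 0.03 (scikit-image backend).  `data_range` defaults to the
reference maximum for float images and 255 for integer images; metrics are
computed on whole images, not masked regions.

## Problem sizes

Tests and the acceptance script use 12²–48² images for exact
oracle-equivalence checks, 128² phantoms with 5 seeds for denoising
quality, and 256² phantoms with 20 seeds per level for noise-estimator
recovery — sizes at which the Monte-Carlo medians are stable while the
whole suite remains quick to run.
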