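"""Per-pixel search-window selection: the adaptive FANLM denoiser.

A fixed search window is a compromise: large windows average more pixels and
suppress noise best in smooth regions, but blur texture; small windows
preserve edges but under-smooth flat areas.  The adaptive scheme runs classic
NLM at three candidate window sizes (7, 13, 21 by default), then picks, per
pixel, the size whose filtered local variance best matches the estimated
noise-free local variance of the input:

    signal variance     sigma_g,c^2 = max(sigma_f,c^2 - sigma_n^2, 0)
    selection criterion size(S_i)   = argmin_c | sigma_g,c^2 - sigma_nlm,c^2 |

where sigma_f,c^2 is the local variance of the noisy image over window c,
sigma_n^2 the (global) corrected Rician noise variance, and sigma_nlm,c^2 the
local variance of the c-filtered image over window c.  Ties go to the
smallest window (cheapest and most detail-preserving).  The final image is a
per-pixel composition: each output pixel is copied verbatim from the filtered
image of its chosen window size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .exceptions import InvalidInputError, InvalidParameterError
from .nlm import NLMParams, nlm_filter
from .noise import RicianNoiseEstimate, estimate_rician_variance

__all__ = [
    "WINDOW_LABELS",
    "WindowChoiceMap",
    "FanlmResult",
    "local_variance",
    "signal_variance",
    "select_window",
    "fanlm_denoise",
]

#: Index-to-label mapping of the window choice map (0/1/2 = small/medium/large).
WINDOW_LABELS = ("small", "medium", "large")


@dataclass(frozen=True)
class WindowChoiceMap:
    """Per-pixel window choice and the criterion values that produced it.

    ``choice`` holds 0/1/2 for small/medium/large; ``criterion_values`` has
    shape (H, W, 3) with the absolute variance mismatches, so
    ``choice == argmin(criterion_values, axis=-1)`` always holds.
    """

    choice: np.ndarray
    criterion_values: np.ndarray

    def fractions(self) -> dict[str, float]:
        """Fraction of pixels assigned to each window size."""
        n = self.choice.size
        return {
            lab: float(np.count_nonzero(self.choice == k)) / n
            for k, lab in enumerate(WINDOW_LABELS)
        }


@dataclass(frozen=True)
class FanlmResult:
    """Output of the full adaptive pipeline, with all intermediates."""

    denoised: np.ndarray
    choice_map: WindowChoiceMap
    noise_estimate: RicianNoiseEstimate
    filtered: dict[str, np.ndarray]
    h: float


def local_variance(image: np.ndarray, window_side: int) -> np.ndarray:
    """Per-pixel population variance over a square neighbourhood.

    Symmetric (edge-repeating mirror) boundary padding via scipy's
    ``reflect`` mode; divisor is the window pixel count (population
    convention), so a single impulse delta in a zero image gives
    ``8 delta^2 / 81`` at its centre for a 3x3 window.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a 2D image, got shape {arr.shape}")
    if window_side % 2 == 0 or window_side < 3:
        raise InvalidParameterError(
            f"window_side must be odd and >= 3, got {window_side}"
        )
    if window_side > 2 * max(arr.shape) - 1:
        raise InvalidParameterError(
            f"window {window_side} is larger than a "
            f"{arr.shape[0]}x{arr.shape[1]} image requires"
        )
    m = uniform_filter(arr, window_side, mode="reflect")
    m2 = uniform_filter(arr * arr, window_side, mode="reflect")
    return np.maximum(m2 - m * m, 0.0)


def signal_variance(var_map: np.ndarray, sigma_n_sq: float) -> np.ndarray:
    """Noise-free signal variance: ``max(var - sigma_n^2, 0)`` elementwise."""
    if sigma_n_sq < 0:
        raise InvalidParameterError(f"sigma_n_sq must be >= 0, got {sigma_n_sq}")
    return np.maximum(np.asarray(var_map, dtype=np.float64) - sigma_n_sq, 0.0)


def select_window(
    noisy: np.ndarray,
    filtered_small: np.ndarray,
    filtered_medium: np.ndarray,
    filtered_large: np.ndarray,
    sigma_n_sq: float,
    params: NLMParams | None = None,
) -> WindowChoiceMap:
    """Choose the best window size per pixel by local variance matching.

    For each candidate c, the criterion is the absolute difference between
    the estimated noise-free local variance of the noisy input over window c
    and the local variance of the c-filtered image over window c.  The argmin
    over (small, medium, large) wins; exact ties resolve to the smaller
    window.
    """
    params = params or NLMParams()
    noisy = np.asarray(noisy, dtype=np.float64)
    filtered = (filtered_small, filtered_medium, filtered_large)
    for f in filtered:
        if np.asarray(f).shape != noisy.shape:
            raise InvalidInputError(
                f"filtered image shape {np.asarray(f).shape} does not match "
                f"noisy image shape {noisy.shape}"
            )
    crit = np.empty(noisy.shape + (3,), dtype=np.float64)
    for k, (f, side) in enumerate(zip(filtered, params.window_sides)):
        g = signal_variance(local_variance(noisy, side), sigma_n_sq)
        n = local_variance(np.asarray(f, dtype=np.float64), side)
        crit[..., k] = np.abs(g - n)
    # np.argmin returns the first minimum, i.e. the smallest window on ties
    choice = np.argmin(crit, axis=-1).astype(np.int8)
    return WindowChoiceMap(choice=choice, criterion_values=crit)


def _select_window_global(
    noisy: np.ndarray,
    filtered: tuple[np.ndarray, np.ndarray, np.ndarray],
    sigma_n_sq: float,
) -> WindowChoiceMap:
    """Image-wide variant: one MAD-based variance per filtered image.

    The criterion compares the global noise-free variance of the input with
    the wavelet-MAD Rician variance of each filtered image, yielding a single
    window choice broadcast to every pixel.
    """
    g = max(float(np.var(noisy)) - sigma_n_sq, 0.0)
    crit_vals = np.empty(3, dtype=np.float64)
    for k, f in enumerate(filtered):
        crit_vals[k] = abs(g - estimate_rician_variance(f).sigma_n_sq)
    best = int(np.argmin(crit_vals))
    choice = np.full(np.asarray(noisy).shape, best, dtype=np.int8)
    crit = np.broadcast_to(crit_vals, choice.shape + (3,)).copy()
    return WindowChoiceMap(choice=choice, criterion_values=crit)


def fanlm_denoise(
    noisy: np.ndarray,
    params: NLMParams | None = None,
    mode: str = "local",
    noise_estimate: RicianNoiseEstimate | None = None,
) -> FanlmResult:
    """Full adaptive pipeline: estimate noise, filter at 3 sizes, compose.

    Parameters
    ----------
    params : NLM parameters; ``params.h`` of ``None`` derives the bandwidth
        as ``h_factor * sigma_n`` from the noise estimate.
    mode : "local" selects per pixel from per-pixel local variances
        (default); "global" makes a single image-wide choice from the
        MAD variance of each filtered image.
    noise_estimate : reuse a precomputed estimate instead of re-estimating.

    Returns a :class:`FanlmResult`; ``denoised`` is the per-pixel composition
    of the three filtered images indexed by the choice map, so every output
    pixel bitwise equals the corresponding pixel of one filtered image.
    """
    if mode not in ("local", "global"):
        raise InvalidParameterError(f"mode must be 'local' or 'global', got {mode!r}")
    params = params or NLMParams()
    v = np.asarray(noisy, dtype=np.float64)
    est = noise_estimate or estimate_rician_variance(v)
    if est.sigma_n_sq == 0.0:
        # noise-free input: nothing to smooth, every window is a no-op choice
        choice = np.zeros(v.shape, dtype=np.int8)
        crit = np.zeros(v.shape + (3,), dtype=np.float64)
        cmap = WindowChoiceMap(choice=choice, criterion_values=crit)
        filtered = {lab: v.copy() for lab in WINDOW_LABELS}
        return FanlmResult(denoised=v.copy(), choice_map=cmap,
                           noise_estimate=est, filtered=filtered, h=0.0)
    h = params.h if params.h is not None else params.h_factor * est.sigma_n
    p = params.with_h(h)
    f_s, f_m, f_l = (nlm_filter(v, side, p) for side in p.window_sides)
    if mode == "local":
        cmap = select_window(v, f_s, f_m, f_l, est.sigma_n_sq, p)
    else:
        cmap = _select_window_global(v, (f_s, f_m, f_l), est.sigma_n_sq)
    denoised = np.choose(cmap.choice, (f_s, f_m, f_l))
    return FanlmResult(
        denoised=denoised,
        choice_map=cmap,
        noise_estimate=est,
        filtered={"small": f_s, "medium": f_m, "large": f_l},
        h=h,
    )
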