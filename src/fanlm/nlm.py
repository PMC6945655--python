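"""Classic non-local means (NLM) filtering with a configurable search window.

Each output pixel is a weighted average of pixels inside a square search
window centred on it,

    u_hat(i) = sum_{j in S_i} w(i, j) v(j),
    w(i, j)  = exp(-||p(N_i) - p(N_j)||^2_{2,a} / h^2) / z(i),

where the patch distance is the Gaussian-kernel-weighted squared L2 distance
between the square patches around i and j, and z(i) normalises the weights to
sum to 1.  Output pixels are therefore convex combinations of input pixels.

Conventions (documented because they fix exact numerical behaviour):

* Patches use reflect (mirror) boundary padding.
* The search window is clipped at the image boundary: only positions j that
  fall inside the image contribute.
* The patch kernel is a normalised (sum 1) isotropic Gaussian of standard
  deviation ``kernel_std_a`` sampled on the patch grid.
* The self weight w(i, i) is, by default, set to the maximum of the other
  weights in the window before normalisation (the usual NLM convention that
  prevents the trivially perfect self-match from dominating); the literal
  ``exp(0) = 1`` rule is available via ``self_weight="exp"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import correlate1d

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = ["NLMParams", "patch_kernel", "patch_distance", "nlm_filter"]


@dataclass(frozen=True)
class NLMParams:
    """Parameters shared by the NLM passes.

    ``h`` is the smoothing bandwidth in intensity units; when ``None`` the
    adaptive pipeline derives it as ``h_factor * sigma_n`` from the noise
    estimate.  The three window side lengths (7, 13, 21) are the small /
    medium / large search-window candidates.
    """

    patch_radius: int = 2
    h: float | None = None
    h_factor: float = 1.2
    kernel_std_a: float = 1.0
    window_small: int = 7
    window_medium: int = 13
    window_large: int = 21
    self_weight: str = "max"

    def __post_init__(self) -> None:
        if self.patch_radius < 1:
            raise InvalidParameterError("patch_radius must be >= 1")
        if self.h is not None and self.h <= 0:
            raise InvalidParameterError("h must be > 0")
        if self.kernel_std_a <= 0:
            raise InvalidParameterError("kernel_std_a must be > 0")
        sides = (self.window_small, self.window_medium, self.window_large)
        if any(s % 2 == 0 or s < 3 for s in sides):
            raise InvalidParameterError("window sides must be odd and >= 3")
        if not self.window_small < self.window_medium < self.window_large:
            raise InvalidParameterError(
                "window sides must satisfy small < medium < large"
            )
        if self.self_weight not in ("max", "exp"):
            raise InvalidParameterError("self_weight must be 'max' or 'exp'")

    @property
    def window_sides(self) -> tuple[int, int, int]:
        return (self.window_small, self.window_medium, self.window_large)

    def with_h(self, h: float) -> "NLMParams":
        return replace(self, h=h)


def _kernel_1d(radius: int, std: float) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x * x) / (2.0 * std * std))
    return g / g.sum()


def patch_kernel(params: NLMParams) -> np.ndarray:
    """The normalised 2D Gaussian patch-weighting kernel (sums to 1)."""
    g = _kernel_1d(params.patch_radius, params.kernel_std_a)
    return np.outer(g, g)


def _check_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a 2D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("image contains non-finite values")
    return arr


def patch_distance(
    image: np.ndarray, i: tuple[int, int], j: tuple[int, int], params: NLMParams
) -> float:
    """Gaussian-weighted squared L2 distance between the patches at i and j.

    Patches are read from the reflect-padded image, so any in-bounds centres
    are valid.  Symmetric in (i, j) and zero iff the patches are identical.
    """
    arr = _check_image(image)
    pr = params.patch_radius
    padded = np.pad(arr, pr, mode="reflect")
    k = patch_kernel(params)

    def patch(c: tuple[int, int]) -> np.ndarray:
        r, q = int(c[0]) + pr, int(c[1]) + pr
        return padded[r - pr:r + pr + 1, q - pr:q + pr + 1]

    d = patch(i) - patch(j)
    return float(np.sum(k * d * d))


def nlm_filter(image: np.ndarray, window_side: int, params: NLMParams) -> np.ndarray:
    """Non-local means with a ``window_side`` x ``window_side`` search window.

    Exact sliding-window evaluation: every offset in the window is visited
    and its Gaussian-weighted patch distance computed by separable
    correlation, which is numerically identical to the per-pixel double loop.
    Constant images are exact fixed points (weights are normalised to 1).
    """
    v = _check_image(image)
    if window_side % 2 == 0 or window_side < 3:
        raise InvalidParameterError(
            f"window_side must be odd and >= 3, got {window_side}"
        )
    if params.h is None:
        raise InvalidParameterError(
            "params.h is not set; use params.with_h(...) or the adaptive "
            "pipeline, which derives h from the noise estimate"
        )
    h2 = float(params.h) ** 2
    pr = params.patch_radius
    wr = window_side // 2
    H, W = v.shape
    if window_side > 2 * max(H, W) - 1:
        raise InvalidParameterError(
            f"window {window_side} is larger than a {H}x{W} image requires "
            f"(a {2 * max(H, W) - 1} window already covers every pixel)"
        )
    pad = pr + wr
    g = _kernel_1d(pr, params.kernel_std_a)
    big = np.pad(v, pad, mode="reflect")
    # patch-padded view: pixel (r, c) of the image sits at (r + pr, c + pr)
    base = big[wr:wr + H + 2 * pr, wr:wr + W + 2 * pr]

    wsum = np.zeros((H, W))
    vsum = np.zeros((H, W))
    wmax = np.zeros((H, W))
    for ty in range(-wr, wr + 1):
        for tx in range(-wr, wr + 1):
            if ty == 0 and tx == 0:
                continue
            shifted = big[wr + ty:wr + ty + H + 2 * pr,
                          wr + tx:wr + tx + W + 2 * pr]
            diff = base - shifted
            diff *= diff
            d = correlate1d(diff, g, axis=0, mode="constant")
            d = correlate1d(d, g, axis=1, mode="constant")
            w = np.exp(-d[pr:pr + H, pr:pr + W] / h2)
            # window clipping: only offsets that land inside the image count
            y0, y1 = max(0, -ty), H - max(0, ty)
            x0, x1 = max(0, -tx), W - max(0, tx)
            wv = w[y0:y1, x0:x1]
            wsum[y0:y1, x0:x1] += wv
            # accumulate w * (v(j) - v(i)): the difference form keeps
            # constant images bitwise fixed points of the filter
            vsum[y0:y1, x0:x1] += wv * (
                v[y0 + ty:y1 + ty, x0 + tx:x1 + tx] - v[y0:y1, x0:x1]
            )
            np.maximum(wmax[y0:y1, x0:x1], wv, out=wmax[y0:y1, x0:x1])

    w_self = wmax if params.self_weight == "max" else np.ones((H, W))
    denom = wsum + w_self  # the self term contributes 0 to the numerator
    return np.where(denom > 0, v + vsum / np.where(denom > 0, denom, 1.0), v)
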