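"""Image-quality metrics: PSNR and SSIM against a reference image.

PSNR is ``10 log10(data_range^2 / MSE)`` in decibels; identical images have
zero MSE and report ``inf``.  SSIM is the standard mean of local structural
similarity with an 11-tap Gaussian window (sigma 1.5) and stability constants
``(K1, K2) = (0.01, 0.03)`` scaled by the data range; it equals 1 exactly for
identical images and can be negative for anti-correlated structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = ["QualityReport", "psnr", "ssim", "evaluate"]

#: Side of the Gaussian SSIM window; images must be at least this large.
SSIM_WINDOW_SIDE = 11


def _resolve_range(reference: np.ndarray, data_range: float | None) -> float:
    if data_range is not None:
        if data_range <= 0:
            raise InvalidParameterError(f"data_range must be > 0, got {data_range}")
        return float(data_range)
    if np.issubdtype(np.asarray(reference).dtype, np.integer):
        return 255.0
    mx = float(np.max(reference))
    if mx <= 0:
        raise InvalidParameterError(
            "cannot infer data_range from a non-positive reference image; "
            "pass data_range explicitly"
        )
    return mx


def _check_pair(reference: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(reference, dtype=np.float64)
    b = np.asarray(test, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError(
            f"reference shape {a.shape} does not match test shape {b.shape}"
        )
    return a, b


@dataclass(frozen=True)
class QualityReport:
    """PSNR (dB), SSIM and the data range they were computed with."""

    psnr_db: float
    ssim: float
    data_range: float


def psnr(reference: np.ndarray, test: np.ndarray,
         data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images.

    ``data_range`` defaults to the reference maximum for float images and
    255 for integer images.
    """
    a, b = _check_pair(reference, test)
    r = _resolve_range(reference, data_range)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(r * r / mse)


def ssim(reference: np.ndarray, test: np.ndarray,
         data_range: float | None = None) -> float:
    """Mean local structural similarity in [-1, 1]; 1 iff identical."""
    a, b = _check_pair(reference, test)
    if min(a.shape) < SSIM_WINDOW_SIDE:
        raise InvalidInputError(
            f"images must be at least {SSIM_WINDOW_SIDE} pixels per axis for "
            f"the SSIM window, got {a.shape}"
        )
    r = _resolve_range(reference, data_range)
    return float(
        structural_similarity(
            a, b, data_range=r, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
    )


def evaluate(reference: np.ndarray, test: np.ndarray,
             data_range: float | None = None) -> QualityReport:
    """Compute both metrics with a shared data range."""
    r = _resolve_range(reference, data_range)
    return QualityReport(
        psnr_db=psnr(reference, test, r), ssim=ssim(reference, test, r),
        data_range=r,
    )
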