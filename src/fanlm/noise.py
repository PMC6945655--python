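"""Rician noise-level estimation for magnitude MR images.

The estimator proceeds in three steps:

1. **Wavelet MAD.** A single-level 2D discrete wavelet transform (Haar by
   default) isolates the diagonal detail (HH) sub-band, which is dominated by
   noise.  The robust standard-deviation estimate is

       sigma_mad = median(|HH|) / 0.6745

   where 0.6745 is the 75th percentile of the standard normal, making the
   estimator unbiased for Gaussian noise.

2. **Fixed-point SNR.** Magnitude images are Rician, not Gaussian: the
   measured fluctuation of the magnitude signal depends on the local
   signal-to-noise ratio theta.  The analytic correction factor

       zeta(theta) = 2 + theta^2
                     - (pi/8) exp(-theta^2/2)
                       * ((2 + theta^2) I0(theta^2/4) + theta^2 I1(theta^2/4))^2

   relates the magnitude variance to the Gaussian channel variance
   (zeta(0) = 2 - pi/2 in the pure-noise Rayleigh regime, zeta -> 1 at high
   SNR).  theta is obtained by iterating

       theta_i = sqrt( zeta(theta_{i-1}) * (1 + mbar0^2 / sigma_mad^2) - 2 )

   to convergence (|theta_i - theta_{i-1}| <= eps, eps = 1e-8), where mbar0
   is the average signal of the data.  A negative radicand means the measured
   signal ratio is below what pure noise would produce, so theta is clamped
   to 0 (the iteration then converges at 0).

3. **Corrected variance.** sigma_n^2 = zeta(theta) * sigma_mad^2.

The modified Bessel functions are evaluated in exponentially scaled form so
zeta never overflows at large theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.special import ive

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "RicianNoiseEstimate",
    "wavelet_hh",
    "mad_sigma",
    "zeta",
    "estimate_snr",
    "estimate_rician_variance",
]

#: 75th percentile of the standard normal; median(|N(0,1)|) = 0.6745.
MAD_SCALE = 0.6745

#: Convergence tolerance of the SNR fixed-point iteration.
DEFAULT_EPS = 1.0e-8

DEFAULT_MAX_ITER = 500


@dataclass(frozen=True)
class RicianNoiseEstimate:
    """Full record of a Rician noise estimate, including intermediates.

    Attributes
    ----------
    sigma_mad : wavelet-MAD standard deviation of the magnitude image.
    theta : converged signal-to-noise ratio (dimensionless, >= 0).
    zeta_value : correction factor zeta(theta) in (0, 2].
    sigma_n_sq : corrected noise variance.
    mean_signal : the average signal mbar0 used in the fixed point.
    n_iterations : fixed-point iterations performed.
    converged : whether |theta_i - theta_{i-1}| <= eps was reached.
    """

    sigma_mad: float
    theta: float
    zeta_value: float
    sigma_n_sq: float
    mean_signal: float
    n_iterations: int
    converged: bool

    @property
    def sigma_n(self) -> float:
        """Corrected noise standard deviation sqrt(sigma_n_sq)."""
        return math.sqrt(self.sigma_n_sq)


def wavelet_hh(image: np.ndarray, wavelet: str = "haar") -> np.ndarray:
    """Single-level diagonal-detail (HH) coefficients of a 2D image.

    Boundary handling is PyWavelets' symmetric (half-sample mirror)
    extension; for the 2-tap Haar filter an H x W input yields an
    ``ceil(H/2) x ceil(W/2)`` coefficient grid (exactly H/2 x W/2 for even
    dimensions).  For the Haar basis the HH coefficient of a 2x2 block
    ``[[a, b], [c, d]]`` is ``(a - b - c + d) / 2``.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InvalidInputError(
            f"need a 2D image with at least 2 pixels per axis, got shape "
            f"{arr.shape}"
        )
    _, (_, _, hh) = pywt.dwt2(arr, wavelet, mode="symmetric")
    return hh


def mad_sigma(image: np.ndarray, wavelet: str = "haar") -> float:
    """Robust noise standard deviation: median(|HH|) / 0.6745."""
    hh = wavelet_hh(image, wavelet=wavelet)
    return float(np.median(np.abs(hh))) / MAD_SCALE


def zeta(theta: float) -> float:
    """Rician variance correction factor as a function of SNR theta.

    Monotone increasing from ``2 - pi/2`` at theta = 0 to 1 as theta -> inf.
    Uses exponentially scaled Bessel functions (``ive``), so the
    ``exp(-theta^2/2)`` prefactor cancels analytically and large theta cannot
    overflow.
    """
    if not np.isfinite(theta) or theta < 0:
        raise InvalidParameterError(
            f"theta must be finite and >= 0, got {theta!r}"
        )
    t2 = float(theta) * float(theta)
    x = t2 / 4.0
    # exp(-t2/2) * Iv(x)^2 == (ive(v, x))^2 since ive(v, x) = Iv(x) exp(-x)
    s = (2.0 + t2) * ive(0, x) + t2 * ive(1, x)
    return 2.0 + t2 - (math.pi / 8.0) * float(s) * float(s)


def estimate_snr(
    mean_signal: float,
    sigma_mad: float,
    eps: float = DEFAULT_EPS,
    max_iter: int = DEFAULT_MAX_ITER,
    theta0: float | None = None,
) -> tuple[float, int, bool]:
    """Fixed-point iteration for the signal-to-noise ratio theta.

    Iterates ``theta <- sqrt(zeta(theta) * (1 + r^2) - 2)`` with
    ``r = mean_signal / sigma_mad``, starting from ``theta0`` (default: r,
    the naive SNR).  A negative radicand clamps theta to 0; iterating from 0
    in that regime reproduces 0, so the pure-noise case converges immediately.

    Returns ``(theta, n_iterations, converged)``.
    """
    if sigma_mad == 0:
        raise ZeroDivisionError(
            "sigma_mad is zero: the image has no measurable noise, so the "
            "signal-to-noise ratio is undefined"
        )
    if sigma_mad < 0:
        raise InvalidParameterError(f"sigma_mad must be > 0, got {sigma_mad}")
    if eps <= 0:
        raise InvalidParameterError(f"eps must be > 0, got {eps}")
    r2 = (float(mean_signal) / float(sigma_mad)) ** 2
    theta = float(theta0) if theta0 is not None else math.sqrt(r2)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        radicand = zeta(theta) * (1.0 + r2) - 2.0
        new = math.sqrt(radicand) if radicand > 0 else 0.0
        if abs(new - theta) <= eps:
            theta = new
            converged = True
            break
        theta = new
    return theta, n_iter, converged


def _otsu_foreground_mean(arr: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    t = threshold_otsu(arr)
    fg = arr[arr > t]
    return float(fg.mean()) if fg.size else float(arr.mean())


def estimate_rician_variance(
    image: np.ndarray,
    wavelet: str = "haar",
    mask: str = "none",
    eps: float = DEFAULT_EPS,
    max_iter: int = DEFAULT_MAX_ITER,
    correction: str = "multiply",
) -> RicianNoiseEstimate:
    """Estimate the Rician noise variance of a magnitude image.

    Composes the wavelet-MAD estimate, the SNR fixed point and the zeta
    correction; all intermediates are recorded in the returned
    :class:`RicianNoiseEstimate`.

    Parameters
    ----------
    mask : "none" uses the whole-image mean as the average signal mbar0;
        "otsu" restricts the mean to pixels above the Otsu threshold, which
        is useful when a large air background would drag the mean down.
    correction : "multiply" applies ``sigma_n^2 = zeta(theta) * sigma_mad^2``;
        "divide" applies the inverse convention
        ``sigma_n^2 = sigma_mad^2 / zeta(theta)``, which treats sigma_mad as a
        measurement of the (SNR-suppressed) magnitude fluctuation and
        recovers the underlying Gaussian channel sigma.

    A noise-free image (zero MAD) returns a degenerate estimate with
    ``sigma_n_sq = 0``.
    """
    if mask not in ("none", "otsu"):
        raise InvalidParameterError(f"mask must be 'none' or 'otsu', got {mask!r}")
    if correction not in ("multiply", "divide"):
        raise InvalidParameterError(
            f"correction must be 'multiply' or 'divide', got {correction!r}"
        )
    arr = np.asarray(image, dtype=np.float64)
    sigma_mad = mad_sigma(arr, wavelet=wavelet)
    mean_signal = (
        _otsu_foreground_mean(arr) if mask == "otsu" else float(arr.mean())
    )
    if sigma_mad == 0.0:
        return RicianNoiseEstimate(
            sigma_mad=0.0, theta=0.0, zeta_value=1.0, sigma_n_sq=0.0,
            mean_signal=mean_signal, n_iterations=0, converged=True,
        )
    theta, n_iter, converged = estimate_snr(
        mean_signal, sigma_mad, eps=eps, max_iter=max_iter
    )
    z = zeta(theta)
    if correction == "multiply":
        sigma_n_sq = z * sigma_mad * sigma_mad
    else:
        sigma_n_sq = sigma_mad * sigma_mad / z
    return RicianNoiseEstimate(
        sigma_mad=sigma_mad, theta=theta, zeta_value=z, sigma_n_sq=sigma_n_sq,
        mean_signal=mean_signal, n_iterations=n_iter, converged=converged,
    )
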