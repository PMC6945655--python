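"""Synthetic brain-like phantoms and the Rician magnitude-noise model.

Magnitude MR images are formed by taking the modulus of complex k-space data
whose real and imaginary channels each carry zero-mean Gaussian noise of
standard deviation ``sigma``.  The resulting pixel intensities follow a Rician
distribution: Rayleigh where the underlying signal is zero (air) and
approximately Gaussian at high signal-to-noise ratio.  This module generates
piecewise-smooth multi-tissue phantoms with a known ground-truth label map and
corrupts them with that exact magnitude model, so every downstream stage
(noise estimation, denoising, segmentation) can be validated against ground
truth without external data.

Noise levels are quoted as percentages of the peak clean intensity
(the BrainWeb convention): ``p%`` noise means ``sigma = (p/100) * max(clean)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import InvalidParameterError

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "add_rician_noise",
    "percent_to_sigma",
    "add_rician_noise_percent",
    "brain_phantom_spec",
]


@dataclass(frozen=True)
class Ellipse:
    """A filled ellipse in pixel coordinates.

    Parameters
    ----------
    center : (row, col) in pixels.
    semi_axes : (semi-axis along rows, semi-axis along cols) in pixels.
    rotation : counter-clockwise rotation in radians.
    intensity : fill intensity in [0, 1].
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0
    intensity: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a piecewise-smooth phantom.

    Shapes are painted in order: where ellipses overlap, the later shape
    overwrites the earlier one.  ``smoothing_sigma > 0`` applies a Gaussian
    blur to the intensity image (not the label map) to soften tissue edges.
    """

    height: int
    width: int
    shapes: Sequence[Ellipse] = field(default_factory=tuple)
    background_intensity: float = 0.0
    smoothing_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise InvalidParameterError(
                f"phantom dimensions must be at least 16x16, got "
                f"{self.height}x{self.width}"
            )
        for v in (self.background_intensity, *(s.intensity for s in self.shapes)):
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"intensity {v} outside [0, 1]")
        if self.smoothing_sigma < 0:
            raise InvalidParameterError("smoothing_sigma must be >= 0")


@dataclass(frozen=True)
class Phantom:
    """A clean phantom image together with its ground-truth tissue labels.

    ``labels`` assigns 0 to the background and ``k`` to pixels whose final
    (topmost) shape is ``spec.shapes[k - 1]``.
    """

    image: np.ndarray
    labels: np.ndarray


def _ellipse_mask(height: int, width: int, ellipse: Ellipse) -> np.ndarray:
    rows, cols = np.mgrid[0:height, 0:width].astype(np.float64)
    dr = rows - ellipse.center[0]
    dc = cols - ellipse.center[1]
    c, s = np.cos(ellipse.rotation), np.sin(ellipse.rotation)
    u = c * dr + s * dc
    v = -s * dr + c * dc
    a, b = ellipse.semi_axes
    if a <= 0 or b <= 0:
        raise InvalidParameterError("ellipse semi-axes must be positive")
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Render a phantom from its spec; deterministic given the spec.

    Returns the intensity image (float64 in [0, 1]) and the crisp label map.
    """
    image = np.full((spec.height, spec.width), spec.background_intensity,
                    dtype=np.float64)
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    for k, shape in enumerate(spec.shapes, start=1):
        mask = _ellipse_mask(spec.height, spec.width, shape)
        image[mask] = shape.intensity
        labels[mask] = k
    if spec.smoothing_sigma > 0:
        image = gaussian_filter(image, spec.smoothing_sigma, mode="nearest")
    return Phantom(image=image, labels=labels)


def add_rician_noise(
    clean: np.ndarray, sigma: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Corrupt a non-negative image with Rician magnitude noise.

    The clean signal is placed on the real channel and independent Gaussian
    noise of standard deviation ``sigma`` is added to both the real and
    imaginary channels before taking the modulus:

        v = sqrt((u + n1)^2 + n2^2),   n1, n2 ~ N(0, sigma^2) i.i.d.

    ``sigma = 0`` returns ``|u|`` exactly.  Output is always non-negative.
    """
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    u = np.asarray(clean, dtype=np.float64)
    if sigma == 0:
        return np.abs(u)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, u.shape)
    n2 = rng.normal(0.0, sigma, u.shape)
    return np.hypot(u + n1, n2)


def percent_to_sigma(clean: np.ndarray, percent: float) -> float:
    """Map a percent noise level to the Gaussian channel sigma.

    ``p%`` noise is defined relative to the peak clean intensity:
    ``sigma = (p/100) * max(clean)``.
    """
    if percent < 0:
        raise InvalidParameterError(f"noise percent must be >= 0, got {percent}")
    return float(percent) / 100.0 * float(np.max(clean))


def add_rician_noise_percent(
    clean: np.ndarray, percent: float, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, float]:
    """Corrupt with ``percent``% Rician noise; returns ``(noisy, sigma)``."""
    sigma = percent_to_sigma(clean, percent)
    return add_rician_noise(clean, sigma, seed), sigma


def brain_phantom_spec(height: int = 256, width: int = 256,
                       smoothing_sigma: float = 0.0, seed: int = 0) -> PhantomSpec:
    """A default T1-like brain phantom.

    Four tissue-like intensity classes on a faint background floor: an outer
    CSF-dark rim (0.25), a grey-matter shell (0.55), a white-matter core
    (0.80, the brightest tissue), and two dark ventricles (0.25).  Geometry
    scales with the requested size.  The background floor is 0.10 rather than
    pure zero so that the phantom, like a magnitude MR slice, has no exact
    zero-signal region yet still exercises the low-SNR (Rayleigh-leaning)
    regime of the noise estimator.
    """
    h, w = float(height), float(width)
    shapes = (
        Ellipse((0.50 * h, 0.50 * w), (0.46 * h, 0.40 * w), 0.0, 0.25),
        Ellipse((0.50 * h, 0.50 * w), (0.41 * h, 0.35 * w), 0.0, 0.55),
        Ellipse((0.52 * h, 0.50 * w), (0.32 * h, 0.26 * w), 0.10, 0.80),
        Ellipse((0.42 * h, 0.42 * w), (0.09 * h, 0.045 * w), 0.35, 0.25),
        Ellipse((0.42 * h, 0.58 * w), (0.09 * h, 0.045 * w), -0.35, 0.25),
    )
    return PhantomSpec(height=height, width=width, shapes=shapes,
                       background_intensity=0.10,
                       smoothing_sigma=smoothing_sigma, seed=seed)
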