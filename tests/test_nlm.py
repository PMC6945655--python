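"""Non-local means core: patch distances, weights, and the filter itself."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fanlm import (
    InvalidParameterError,
    NLMParams,
    nlm_filter,
    patch_distance,
    patch_kernel,
)


def brute_force_nlm(image, window_side, params):
    """Direct per-pixel double loop over the weight equations.

    Independent of the package's sliding-window implementation: patches are
    read from a reflect-padded copy, the window is clipped at the image
    boundary, weights are exp(-d/h^2) normalised by their sum.  Asserts the
    normalisation at every pixel as it goes.
    """
    H, W = image.shape
    pr, wr = params.patch_radius, window_side // 2
    padded = np.pad(image, pr, mode="reflect")
    x = np.arange(-pr, pr + 1, dtype=float)
    g = np.exp(-(x[:, None] ** 2 + x[None, :] ** 2)
               / (2 * params.kernel_std_a**2))
    g /= g.sum()
    out = np.empty_like(image)
    for i0 in range(H):
        for j0 in range(W):
            p_i = padded[i0:i0 + 2 * pr + 1, j0:j0 + 2 * pr + 1]
            weights = {}
            for di in range(-wr, wr + 1):
                for dj in range(-wr, wr + 1):
                    i1, j1 = i0 + di, j0 + dj
                    if not (0 <= i1 < H and 0 <= j1 < W):
                        continue
                    p_j = padded[i1:i1 + 2 * pr + 1, j1:j1 + 2 * pr + 1]
                    d = float(np.sum(g * (p_i - p_j) ** 2))
                    weights[(i1, j1)] = np.exp(-d / params.h**2)
            if params.self_weight == "max":
                others = [w for key, w in weights.items() if key != (i0, j0)]
                weights[(i0, j0)] = max(others)
            z = sum(weights.values())
            normalised = {key: w / z for key, w in weights.items()}
            assert abs(sum(normalised.values()) - 1.0) < 1e-10
            out[i0, j0] = sum(w * image[i1, j1]
                              for (i1, j1), w in normalised.items())
    return out


class TestPatchDistance:
    def test_same_index_is_zero(self):
        img = np.random.default_rng(0).random((10, 10))
        assert patch_distance(img, (4, 4), (4, 4), NLMParams(h=1.0)) == 0.0

    def test_constant_image_is_zero_everywhere(self):
        img = np.full((10, 10), 2.5)
        assert patch_distance(img, (2, 3), (7, 6), NLMParams(h=1.0)) == 0.0

    def test_center_pixel_difference_scales_by_kernel_center_weight(self):
        params = NLMParams(h=1.0, patch_radius=2)
        delta = 0.7
        img = np.zeros((20, 20))
        img[5, 5] = delta  # patches at (5,5) and (14,14) differ only there
        d = patch_distance(img, (5, 5), (14, 14), params)
        center = patch_kernel(params)[2, 2]
        assert d == pytest.approx(center * delta**2, rel=1e-12)

    def test_symmetric(self):
        img = np.random.default_rng(1).random((12, 12))
        p = NLMParams(h=0.5)
        assert patch_distance(img, (2, 3), (8, 9), p) == pytest.approx(
            patch_distance(img, (8, 9), (2, 3), p), rel=1e-12
        )


class TestNlmFilter:
    def test_constant_image_is_exact_fixed_point(self):
        img = np.full((16, 16), 0.37)
        for side in (7, 13, 21):
            out = nlm_filter(img, side, NLMParams(h=0.1))
            assert np.array_equal(out, img)

    @pytest.mark.parametrize("self_weight", ["exp", "max"])
    @pytest.mark.parametrize("window_side", [7, 23])
    def test_matches_brute_force_oracle(self, self_weight, window_side):
        rng = np.random.default_rng(7)
        img = rng.random((12, 12))
        params = NLMParams(h=0.3, self_weight=self_weight)
        mine = nlm_filter(img, window_side, params)
        oracle = brute_force_nlm(img, window_side, params)
        assert np.max(np.abs(mine - oracle)) < 1e-10

    def test_windowed_equals_full_search_when_window_covers_image(self):
        rng = np.random.default_rng(9)
        img = rng.random((12, 12))
        params = NLMParams(h=0.4)
        # 23 covers every pixel from any centre of a 12x12 image
        assert np.max(np.abs(
            nlm_filter(img, 23, params) - brute_force_nlm(img, 23, params)
        )) < 1e-10

    def test_intensity_shift_equivariance(self):
        # weights depend only on differences, and sum to one: adding a
        # constant to the input must add exactly that constant to the output
        rng = np.random.default_rng(3)
        img = rng.random((16, 16))
        params = NLMParams(h=0.3)
        out = nlm_filter(img, 7, params)
        shifted = nlm_filter(img + 5.0, 7, params)
        assert np.max(np.abs(shifted - (out + 5.0))) < 1e-10

    def test_large_h_tends_to_window_mean(self):
        rng = np.random.default_rng(4)
        img = rng.random((16, 16))
        out = nlm_filter(img, 7, NLMParams(h=1e6, self_weight="exp"))
        # box mean over the clipped window (oracle via masked sums)
        from scipy.ndimage import uniform_filter
        ones = np.ones_like(img)
        num = uniform_filter(img, 7, mode="constant")
        den = uniform_filter(ones, 7, mode="constant")
        assert np.max(np.abs(out - num / den)) < 1e-6

    def test_output_within_input_range(self):
        rng = np.random.default_rng(5)
        img = rng.random((20, 20))
        out = nlm_filter(img, 13, NLMParams(h=0.2))
        assert out.min() >= img.min() - 1e-12
        assert out.max() <= img.max() + 1e-12

    @pytest.mark.parametrize("side", [7, 13, 21])
    def test_reduces_noise_on_constant_background(self, side):
        rng = np.random.default_rng(6)
        img = 0.5 + rng.normal(0, 0.05, (48, 48))
        out = nlm_filter(img, side, NLMParams(h=0.06))
        assert out.var() < img.var()

    @pytest.mark.parametrize("side", [4, 1, -3])
    def test_invalid_window_rejected(self, side):
        with pytest.raises(InvalidParameterError):
            nlm_filter(np.zeros((16, 16)), side, NLMParams(h=1.0))

    def test_oversized_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            nlm_filter(np.zeros((10, 10)), 25, NLMParams(h=1.0))

    def test_missing_h_rejected(self):
        with pytest.raises(InvalidParameterError):
            nlm_filter(np.zeros((16, 16)), 7, NLMParams())

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, (9, 9),
                      elements=st.floats(0.0, 1.0, allow_nan=False)))
    def test_convex_combination_property(self, img):
        out = nlm_filter(img, 5, NLMParams(h=0.5, patch_radius=1))
        assert np.all(out >= img.min() - 1e-12)
        assert np.all(out <= img.max() + 1e-12)
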