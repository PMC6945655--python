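"""Fast robust fuzzy c-means: reconstruction, histogram FCM, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.ndimage import gaussian_filter

from fanlm import (
    FRFCMParams,
    InvalidInputError,
    add_rician_noise_percent,
    filter_memberships,
    frfcm_segment,
    histogram_fcm,
    morph_reconstruct,
)
from .conftest import best_permutation_accuracy


def pixelwise_fcm(pixels, n_clusters, init_centers, m=2.0, tol=1e-10,
                  max_iter=300):
    """Direct FCM over all pixels (no histogram): the independent oracle."""
    x = pixels.ravel().astype(float)
    centers = init_centers.astype(float).copy()
    for _ in range(max_iter):
        d2 = np.maximum((x[:, None] - centers[None, :]) ** 2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))
        mu = inv / inv.sum(axis=1, keepdims=True)
        new = (mu**m * x[:, None]).sum(axis=0) / (mu**m).sum(axis=0)
        delta = np.max(np.abs(new - centers))
        centers = new
        if delta < tol:
            break
    return np.sort(centers)


class TestMorphReconstruct:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 0.6)
        assert np.array_equal(morph_reconstruct(img, 2), img)

    def test_salt_impulse_removed(self):
        img = np.full((9, 9), 0.3)
        img[4, 4] = 0.9
        out = morph_reconstruct(img, 1)
        assert out[4, 4] == pytest.approx(0.3)
        assert np.allclose(out, 0.3)

    def test_pepper_impulse_removed(self):
        img = np.full((9, 9), 0.7)
        img[4, 4] = 0.1
        assert np.allclose(morph_reconstruct(img, 1), 0.7)

    def test_output_within_input_range(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32))
        out = morph_reconstruct(img, 2)
        assert out.min() >= img.min() and out.max() <= img.max()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        img = gaussian_filter(rng.random((40, 40)), 2.0)
        once = morph_reconstruct(img, 3)
        twice = morph_reconstruct(once, 3)
        assert np.max(np.abs(once - twice)) < 1e-12


class TestHistogramFcm:
    def test_two_delta_histogram_converges_to_deltas(self):
        centers, mu, _ = histogram_fcm(
            np.array([10.0, 200.0]), np.array([500.0, 500.0]),
            FRFCMParams(n_clusters=2, tol=1e-9),
        )
        assert np.allclose(centers, [10.0, 200.0], atol=1e-6)

    def test_memberships_sum_to_one(self):
        rng = np.random.default_rng(0)
        levels = np.sort(rng.choice(256, 40, replace=False)).astype(float)
        counts = rng.integers(1, 100, 40).astype(float)
        _, mu, _ = histogram_fcm(levels, counts, FRFCMParams(n_clusters=4))
        assert np.allclose(mu.sum(axis=1), 1.0, atol=1e-10)

    def test_level_at_center_gets_crisp_membership(self):
        levels = np.array([0.0, 50.0, 100.0])
        counts = np.array([10.0, 10.0, 10.0])
        centers, mu, _ = histogram_fcm(
            levels, counts, FRFCMParams(n_clusters=3, max_iter=1),
            init_centers=np.array([0.0, 50.0, 100.0]),
        )
        assert mu[1, 1] == 1.0 and mu[1, 0] == 0.0 and mu[1, 2] == 0.0

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(3)
        levels = np.sort(rng.choice(200, 60, replace=False)).astype(float)
        counts = rng.integers(1, 50, 60).astype(float)
        _, _, trace = histogram_fcm(levels, counts,
                                    FRFCMParams(n_clusters=3, tol=1e-9))
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_matches_pixelwise_fcm_on_few_level_image(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 64, (40, 40)).astype(float)
        levels, counts = np.unique(img, return_counts=True)
        init = np.array([10.0, 30.0, 50.0])
        params = FRFCMParams(n_clusters=3, tol=1e-10, max_iter=300)
        centers, _, _ = histogram_fcm(levels, counts.astype(float), params,
                                      init_centers=init)
        oracle = pixelwise_fcm(img, 3, init)
        assert np.max(np.abs(centers - oracle)) < 1e-6

    def test_too_few_levels_rejected(self):
        with pytest.raises(InvalidInputError):
            histogram_fcm(np.array([1.0, 2.0]), np.array([5.0, 5.0]),
                          FRFCMParams(n_clusters=3))


class TestFilterMemberships:
    def test_uniform_memberships_unchanged(self):
        mu = np.full((12, 12, 3), 1.0 / 3.0)
        assert np.allclose(filter_memberships(mu, 3), mu)

    def test_single_misclassified_pixel_adopts_neighbourhood(self):
        mu = np.zeros((9, 9, 2))
        mu[..., 0] = 1.0
        mu[4, 4] = [0.0, 1.0]
        out = filter_memberships(mu, 3)
        assert out[4, 4, 0] == 1.0 and out[4, 4, 1] == 0.0

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, (8, 8, 3),
                      elements=st.floats(0.0, 1.0, allow_nan=False)))
    def test_sums_renormalised_to_one(self, mu):
        out = filter_memberships(mu, 3)
        assert np.allclose(out.sum(axis=-1), 1.0, atol=1e-10)


class TestFrfcmSegment:
    def test_single_cluster_labels_everything_zero(self):
        rng = np.random.default_rng(0)
        labels, mm = frfcm_segment(rng.random((32, 32)),
                                   FRFCMParams(n_clusters=1))
        assert np.all(labels == 0)
        assert np.all(mm.mu == 1.0)

    def test_labels_agree_with_argmax_memberships(self, three_class_phantom):
        noisy, _ = add_rician_noise_percent(three_class_phantom.image, 5.0, 0)
        labels, mm = frfcm_segment(noisy, FRFCMParams(n_clusters=3))
        assert set(np.unique(labels)) <= {0, 1, 2}
        assert np.array_equal(labels, np.argmax(mm.mu, axis=-1))
        assert np.all(np.diff(mm.centers) >= 0)

    def test_accuracy_on_noisy_three_class_phantom(self, three_class_phantom):
        noisy, _ = add_rician_noise_percent(three_class_phantom.image, 5.0, 1)
        labels, _ = frfcm_segment(noisy, FRFCMParams(n_clusters=3))
        acc = best_permutation_accuracy(three_class_phantom.labels, labels, 3)
        assert acc >= 0.95

    def test_memberships_sum_to_one_after_full_pipeline(self,
                                                        three_class_phantom):
        noisy, _ = add_rician_noise_percent(three_class_phantom.image, 5.0, 2)
        _, mm = frfcm_segment(noisy, FRFCMParams(n_clusters=3))
        assert np.allclose(mm.mu.sum(axis=-1), 1.0, atol=1e-10)

    def test_constant_image_rejected_for_multiple_clusters(self):
        with pytest.raises(InvalidInputError):
            frfcm_segment(np.full((32, 32), 0.5), FRFCMParams(n_clusters=3))
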