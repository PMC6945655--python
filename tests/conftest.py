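import numpy as np
import pytest
from scipy.ndimage import binary_dilation
from scipy.optimize import linear_sum_assignment

from fanlm import Ellipse, PhantomSpec, brain_phantom_spec, make_phantom


@pytest.fixture(scope="session")
def brain128():
    """Default brain-like phantom at 128x128 (image, labels)."""
    return make_phantom(brain_phantom_spec(128, 128))


@pytest.fixture(scope="session")
def three_class_phantom():
    """Piecewise-constant 3-class phantom (0.2 / 0.5 / 0.9) with labels."""
    spec = PhantomSpec(
        128, 128,
        shapes=(
            Ellipse((64, 64), (52, 44), 0.0, 0.5),
            Ellipse((66, 64), (30, 24), 0.2, 0.9),
        ),
        background_intensity=0.2,
    )
    return make_phantom(spec)


def label_edges(labels: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels adjacent to a tissue-label change."""
    edges = np.zeros(labels.shape, dtype=bool)
    edges[:-1, :] |= labels[:-1, :] != labels[1:, :]
    edges[1:, :] |= labels[:-1, :] != labels[1:, :]
    edges[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    edges[:, 1:] |= labels[:, :-1] != labels[:, 1:]
    return edges


def near_edge_mask(labels: np.ndarray, distance: int = 2) -> np.ndarray:
    return binary_dilation(label_edges(labels), iterations=distance)


def best_permutation_accuracy(truth: np.ndarray, predicted: np.ndarray,
                              n_classes: int) -> float:
    """Pixel accuracy after the optimal label permutation."""
    conf = np.array([
        [np.sum((truth == i) & (predicted == j)) for j in range(n_classes)]
        for i in range(n_classes)
    ])
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum()) / truth.size
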