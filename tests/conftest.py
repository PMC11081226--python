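import numpy as np
import pytest

from gafs.data import LabeledDataset


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """3 samples x 2 features, labels {A, B, A}."""
    return LabeledDataset(
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        np.array(["A", "B", "A"], dtype=object),
    )


@pytest.fixture
def separable_gaussians():
    """Two well-separated Gaussian classes, 100 samples each, 2-D."""
    rng = np.random.default_rng(42)
    a = rng.normal([0.0, 0.0], 1.0, size=(100, 2))
    b = rng.normal([6.0, 6.0], 1.0, size=(100, 2))
    X = np.vstack([a, b])
    y = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
    return LabeledDataset(X, y)
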