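import numpy as np
import pytest

from hsimap.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """32x32x8 three-class phantom with moderate speckle (L=4)."""
    return generate_phantom(
        PhantomSpec(height=32, width=32, n_bands=8, n_classes=3,
                    speckle_looks=4.0, seed=11)
    )


@pytest.fixture
def clean_phantom():
    """Noise-free three-class phantom (multiplicative identity limit)."""
    return generate_phantom(
        PhantomSpec(height=32, width=32, n_bands=8, n_classes=3,
                    speckle_looks=None, intra_class_sd=0.0, seed=11)
    )


@pytest.fixture
def blob_features(rng):
    """Sixty 2-D points in three well-separated blobs + their memberships."""
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    labels = np.repeat(np.arange(3), 20)
    X = centers[labels] + rng.normal(0, 0.3, size=(60, 2))
    return X, labels
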