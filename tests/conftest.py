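import numpy as np
import pytest

from specsplit.data import SpectralDataset
from specsplit.simulate import make_fixture


@pytest.fixture
def tiny_ds() -> SpectralDataset:
    """3 samples x 4 variables, two classes, fixed values."""
    return SpectralDataset(
        intensities=np.array([[1.0, 2.0, 3.0, 4.0],
                              [0.5, 1.5, 2.5, 3.5],
                              [4.0, 3.0, 2.0, 1.0]]),
        wavenumbers=np.array([1000.0, 1100.0, 1200.0, 1300.0]),
        labels=np.array(["a", "a", "b"], dtype=object),
        sample_ids=np.array(["s0", "s1", "s2"], dtype=object),
    )


@pytest.fixture
def blobs_ds() -> SpectralDataset:
    """Two well-separated Gaussian blobs, 10 samples each, 5 variables."""
    return make_fixture(n_per_class=10, n_vars=5, separation=10.0, seed=7)


@pytest.fixture
def line_1d_ds() -> SpectralDataset:
    """Four 1-D samples at 0, 1, 2, 10 (single class)."""
    return SpectralDataset(
        intensities=np.array([[0.0], [1.0], [2.0], [10.0]]),
        wavenumbers=np.array([1.0]),
        labels=np.array(["a"] * 4, dtype=object),
        sample_ids=np.array([f"s{i}" for i in range(4)], dtype=object),
    )


def random_dataset(rng: np.random.Generator, n_per_class=(5, 5), n_vars=4
                   ) -> SpectralDataset:
    """Random multi-class dataset helper used by several test modules."""
    blocks, labels = [], []
    for c, n in enumerate(n_per_class):
        blocks.append(rng.standard_normal((n, n_vars)))
        labels += [f"class_{c}"] * n
    n_tot = sum(n_per_class)
    return SpectralDataset(
        intensities=np.vstack(blocks),
        wavenumbers=np.arange(1.0, n_vars + 1),
        labels=np.asarray(labels, dtype=object),
        sample_ids=np.asarray([f"s{i}" for i in range(n_tot)], dtype=object),
    )
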