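import numpy as np
import pytest

from mfcrad.synthetic import generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """One mid-sized phantom on a 64^3 grid (fast, reused read-only)."""
    return generate_phantom(
        shape=(64, 64, 64), tumor_volume_cc=2.0, heterogeneity=1.0,
        mean_shift_hu=0.0, seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bar_roi(bins_1d, n_bins=2):
    """A 1x1xN ROI with the given bin values (the worked micro-examples)."""
    from mfcrad.radiomics.discretize import DiscretizedROI

    arr = np.asarray(bins_1d, dtype=np.int32).reshape(1, 1, -1)
    return DiscretizedROI(bins=arr, mask=np.ones_like(arr, dtype=np.uint8), n_bins=n_bins)
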