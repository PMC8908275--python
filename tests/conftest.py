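import numpy as np
import pytest

from sadt import BinaryMask, DwiSeries, ImageGrid, default_tumour_phantom, tumour_manual_mask


@pytest.fixture
def small_grid():
    return ImageGrid(shape=(8, 8, 4), spacing=(1.82, 1.82, 5.0))


@pytest.fixture
def mono_exponential_series(small_grid):
    """Noiseless mono-exponential series with spatially varying ADC/S0."""
    rng = np.random.default_rng(11)
    adc = rng.uniform(0.5e-3, 2.5e-3, small_grid.shape)
    s0 = rng.uniform(200.0, 1200.0, small_grid.shape)
    bvals = np.array([0.0, 170.0, 500.0, 1100.0])
    signal = s0[..., None] * np.exp(-bvals * adc[..., None])
    series = DwiSeries(signal, bvals, small_grid)
    return series, adc, s0


@pytest.fixture(scope="session")
def noiseless_phantom():
    return default_tumour_phantom(seed=0, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_phantom():
    # SNR 30 at b=0 in background tissue (S0 600 / sigma 20)
    return default_tumour_phantom(seed=3, noise_sigma=20.0)


@pytest.fixture(scope="session")
def generous_mask(noiseless_phantom):
    _, truth = noiseless_phantom
    return tumour_manual_mask(truth)


def random_mask(rng, grid, p=0.5):
    return BinaryMask(rng.random(grid.shape) < p, grid)
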