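import numpy as np
import pytest

from atrigg import simulate
from atrigg.spectra_io import WavenumberGrid


@pytest.fixture(scope="session")
def default_grid() -> WavenumberGrid:
    return simulate.make_default_grid(4.0)


@pytest.fixture(scope="session")
def coarse_grid() -> WavenumberGrid:
    """Small grid for fast filter/region tests."""
    return simulate.make_default_grid(50.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Quiet, quick dataset: 30 samples x 5 replicates, no outliers."""
    config = simulate.recovery_config(seed=7, n_samples=30, outlier_rate=0.0)
    return simulate.simulate_dataset(config)


def dataset_spectra(dataset):
    return {r.sample_id: m for r, m in zip(dataset.samples, dataset.spectra)}
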