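import numpy as np
import pytest

from stemchron.io import CalCurve
from stemchron.simulate import SimConfig, make_bomb_curve, simulate_dataset


@pytest.fixture(scope="session")
def bomb_curve() -> CalCurve:
    return make_bomb_curve()


@pytest.fixture(scope="session")
def linear_curve() -> CalCurve:
    """mu(t) = 100 + (t - 1950), no curve error: unit pMC/yr slope."""
    year = np.arange(1900.0, 2010.0, 0.5)
    return CalCurve(year, 100.0 + (year - 1950.0), np.zeros_like(year))


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One seeded default dataset shared by the slower end-to-end tests."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
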