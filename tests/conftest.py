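import numpy as np
import pytest

from gpflm.fpca import CurveSet
from gpflm.model import logit_family
from gpflm.simulation import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def logit():
    return logit_family()


@pytest.fixture(scope="session")
def cosine_basis():
    """Orthonormal cosine pair on [0, 1], 101 points, used as FPCA truth."""
    grid = np.linspace(0.0, 1.0, 101)
    phi = np.sqrt(2.0) * np.cos(np.arange(1, 3)[:, None] * np.pi * grid[None, :])
    return grid, phi


@pytest.fixture(scope="session")
def small_dataset():
    """Well-conditioned simulated sample shared by several tests."""
    config = SimConfig(n=400, seed=5, coef_scale=0.2, center_z3=True)
    return simulate_dataset(config, seed=5)


@pytest.fixture()
def random_curves():
    rng = np.random.default_rng(42)
    grid = np.sort(rng.uniform(0.0, 1.0, size=15))
    values = rng.normal(size=(12, 15))
    return CurveSet(grid, values)
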