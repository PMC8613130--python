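import numpy as np
import pytest

from smcimpute.data import MultilevelDataset


@pytest.fixture
def toy_dataset():
    """Three clusters of three rows; x level-1, z level-2, complete."""
    cluster = np.repeat(["a", "b", "c"], 3)
    x = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 8.0, -1.0, 0.0, 1.0])
    z = np.repeat([2.0, -1.0, 0.5], 3)
    y = np.arange(9, dtype=float)
    return MultilevelDataset({"x": x, "z": z, "y": y}, cluster,
                             {"x": 1, "z": 2, "y": 1})


@pytest.fixture
def incomplete_dataset():
    """Two clusters, one missing x cell per cluster."""
    cluster = np.repeat([0, 1], 4)
    x = np.array([1.0, np.nan, 2.0, 0.5, -1.0, 0.3, np.nan, 0.2])
    z = np.repeat([1.0, -0.5], 4)
    y = np.array([0.2, 1.0, -0.3, 0.8, 0.1, -0.6, 0.4, 0.0])
    return MultilevelDataset({"x": x, "z": z, "y": y}, cluster,
                             {"x": 1, "z": 2, "y": 1})


def random_dataset(rng, J=6, n=5, missing_frac=0.0):
    cluster = np.repeat(np.arange(J), n)
    x = rng.standard_normal(J * n)
    z = np.repeat(rng.standard_normal(J), n)
    y = rng.standard_normal(J * n)
    if missing_frac:
        m = rng.random(J * n) < missing_frac
        x = x.copy()
        x[m] = np.nan
    return MultilevelDataset({"x": x, "z": z, "y": y}, cluster,
                             {"x": 1, "z": 2, "y": 1})
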