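import numpy as np
import pytest

from neurorhythm.integrate import build_grid, generate_dataset
from neurorhythm.models import make_pdi_model


@pytest.fixture(scope="session")
def default_grid():
    return build_grid(0.0, 5.0, 0.02)


@pytest.fixture(scope="session")
def model1():
    return make_pdi_model(1)


@pytest.fixture(scope="session")
def model1_dataset(model1, default_grid):
    return generate_dataset(model1, np.array([1.0, 1.0, 1.0]), default_grid, model_id=1)


@pytest.fixture(scope="session")
def small_dataset(model1):
    """Coarse model-1 dataset for cheap training tests."""
    grid = build_grid(0.0, 5.0, 0.1)
    return generate_dataset(model1, np.array([1.0, 1.0, 1.0]), grid, model_id=1)


def random_quadratic_model(rng, k):
    """Small random structured model with symmetric quadratic forms."""
    from neurorhythm.models import QuadraticODEModel

    c = rng.normal(size=k)
    A = rng.normal(size=(k, k))
    B = rng.normal(size=(k, k, k)) * 0.1
    B = (B + np.swapaxes(B, 1, 2)) / 2
    return QuadraticODEModel(c=c, A=A, B=B)
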