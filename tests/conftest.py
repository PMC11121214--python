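import numpy as np
import pytest

from iondetail.icsd import ICSD
from iondetail.synth import SyntheticStudySpec, default_grid_set, generate_survival_dataset


def random_icsd(rng: np.random.Generator, nu_max: int | None = None) -> ICSD:
    """A random dense ICSD (Dirichlet weights over 0..nu_max)."""
    if nu_max is None:
        nu_max = int(rng.integers(2, 40))
    probs = rng.dirichlet(np.full(nu_max + 1, 0.5))
    return ICSD(probs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240507)


@pytest.fixture(scope="session")
def grid_set():
    """Quantity grids for the three-diameter target scan (session-cached)."""
    return default_grid_set()


@pytest.fixture(scope="session")
def grid_set_true():
    """Grids restricted to the ground-truth 2.3 x 3.4 nm geometry."""
    return default_grid_set(diameters_nm=[2.3])


@pytest.fixture(scope="session")
def noise_free_records():
    return generate_survival_dataset(SyntheticStudySpec(seed=1))
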