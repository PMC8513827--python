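import numpy as np
import pytest

from phenomem import CompartmentState, ModelParams, SSAConfig, generate_fixtures
from phenomem.ssa_engine import sample_residence_times


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The seeded fixture set, generated once per session."""
    outdir = tmp_path_factory.mktemp("fixtures")
    generate_fixtures(seed=0, outdir=outdir)
    return outdir


@pytest.fixture(scope="session")
def residence_n4():
    """10,000 first-passage times, n_on = 4, epsilon = 0.3 (fixed seed)."""
    return sample_residence_times(4, 0.3, 10_000, SSAConfig(seed=42))


@pytest.fixture
def symmetric_params():
    return ModelParams(n_on=4, mu=0.2, epsilon=0.5, birth=1.0, death=0.98)


@pytest.fixture
def all_off_start(symmetric_params):
    return CompartmentState.all_off(symmetric_params.n_on, 1000.0)


def random_params(rng: np.random.Generator, symmetric: bool = False) -> ModelParams:
    n = int(rng.integers(1, 12))
    if symmetric:
        birth = float(rng.uniform(0, 2))
        death = float(rng.uniform(0, 2))
    else:
        birth = rng.uniform(0, 2, n + 1)
        death = rng.uniform(0, 2, n + 1)
    return ModelParams(n_on=n, mu=float(rng.uniform(0, 1)),
                       epsilon=float(rng.uniform(0.05, 2)),
                       birth=birth, death=death)
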