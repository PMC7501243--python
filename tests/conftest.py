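import numpy as np
import pytest

from fmtkit.protocol import default_timeline
from fmtkit.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def timeline():
    return default_timeline()


@pytest.fixture(scope="session")
def small_cohort(timeline):
    """200-molecule mixed cohort shared across classification tests."""
    spec = CohortSpec(n_molecules=200, seed=1234)
    arch, truth = simulate_cohort(spec, timeline)
    return arch, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
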