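import numpy as np
import pytest

from prsx.model import PRSDecomposition
from prsx.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A 200-sample cohort with all three mapping stages planted."""
    return simulate(SimConfig(n_samples=200, seed=11))


@pytest.fixture(scope="session")
def fitted(small_sim):
    model = PRSDecomposition(
        small_sim.panel, small_sim.scoring, small_sim.gwas,
        small_sim.annotation, small_sim.cs2g,
    )
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
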