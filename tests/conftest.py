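import numpy as np
import pytest

from annealtree.synthetic_data import SimulationParams, evolve_alignment, toy_fixtures


@pytest.fixture(scope="session")
def toys():
    return toy_fixtures()


@pytest.fixture(scope="session")
def syn12():
    """12-taxon, 400-site alignment with mild homoplasy and its true tree."""
    return evolve_alignment(SimulationParams(12, 400, p=0.05, seed=42, name="syn12"))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
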