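import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import placecell as pc

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    """A small synthetic traversal library shared across tests."""
    return pc.synthesize_traversal_library(20, seed=7)


@pytest.fixture(scope="session")
def loco(library):
    """15-traversal locomotion trace."""
    return pc.assemble_locomotion(library, 15, seed=8)


@pytest.fixture(scope="session")
def mask(loco):
    return pc.running_mask(loco.velocity)


@pytest.fixture(scope="session")
def small_population(loco):
    """5 place + 15 noise cells on the shared locomotion trace."""
    pop = pc.PopulationSpec(n_place=5, n_nonplace=15)
    return pc.build_population(pop, loco, seed=9)
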