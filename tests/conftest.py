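import numpy as np
import pytest
from hypothesis import settings

from sonoflex import klm
from sonoflex.materials import AIR, WATER

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_stack():
    """Reference air-backed pillar-transducer design, water-loaded."""
    return klm.reference_design()


@pytest.fixture(scope="session")
def ref_stack_air():
    return klm.reference_design(load=AIR)


@pytest.fixture(scope="session")
def grid():
    """Coarser frequency grid for fast model evaluations in tests."""
    return klm.default_grid(n=1024)


@pytest.fixture(scope="session")
def ref_transmit(ref_stack, grid):
    return klm.transmit_transfer(ref_stack, grid)
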