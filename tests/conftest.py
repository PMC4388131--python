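import numpy as np
import pytest

from gridpi import PIField, hexagonal_arena
from gridpi.multiroom import build_multiroom


@pytest.fixture(scope="session")
def hex_arena():
    return hexagonal_arena()


@pytest.fixture()
def pi_signed(hex_arena):
    return PIField.for_arena(hex_arena)


@pytest.fixture(scope="session")
def multiroom_setup():
    """The trained two-room fixture (19 places, NLMS readout learned)."""
    return build_multiroom()
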