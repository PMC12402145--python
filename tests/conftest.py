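import numpy as np
import pytest

from plaquetime.isotopes import (
    ABETA42_SEQUENCE,
    EnrichmentParams,
    composition_from_sequence,
    isotopologue_pattern,
)


@pytest.fixture(scope="session")
def abeta_comp():
    return composition_from_sequence(ABETA42_SEQUENCE)


@pytest.fixture(scope="session")
def abeta_natural_pattern(abeta_comp):
    return isotopologue_pattern(abeta_comp, EnrichmentParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
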