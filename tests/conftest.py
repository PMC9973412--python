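"""Shared fixtures: toy sequences, small seeded simulations."""

import numpy as np
import pytest

from snvscreen import CodingSequence, enumerate_snv_space
from snvscreen.simulate import scenario_from_dict


@pytest.fixture
def toy_cds():
    return CodingSequence(id="toy", sequence="ATGTAA", includes_stop=True)


@pytest.fixture
def small_cds():
    # 8 codons incl. stop; mixed composition, no internal stops
    return CodingSequence(
        id="small", sequence="ATGGCTCGTAAACCGTGGTCTTAA", includes_stop=True
    )


@pytest.fixture
def small_space(small_cds):
    return enumerate_snv_space(small_cds)


DEFAULT_SCENARIO_SEED = 1


@pytest.fixture(scope="session")
def default_screen():
    """The default planted-hit scenario at desk scale (shared across tests)."""
    return scenario_from_dict({}, seed=DEFAULT_SCENARIO_SEED)


NEUTRAL_CONFIG = {
    "cds": {"n_codons": 50},
    "n_inserts": 1000,
    "fitness": {"n_activating": 0},
    "sequencing": {"depth": 20000},
    "schedule": {"duration_days": 8, "sampling_days": [8]},
}


@pytest.fixture
def neutral_config():
    return dict(NEUTRAL_CONFIG)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
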