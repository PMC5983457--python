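import numpy as np
import pytest

from pepthalf import (
    HalfLifeDataset,
    PeptideRecord,
    SimulationConfig,
    simulate_dataset,
)


def make_dataset(rows):
    """rows: iterable of (id, sequence, half_life_seconds)."""
    return HalfLifeDataset(
        [PeptideRecord(id=i, sequence=s, half_life_seconds=t) for i, s, t in rows]
    )


@pytest.fixture(scope="session")
def simulated_ds():
    """Default synthetic world: 200 peptides, noise sd 0.5, seed 0."""
    return simulate_dataset(SimulationConfig())


@pytest.fixture(scope="session")
def simulated_noiseless_ds():
    return simulate_dataset(SimulationConfig(noise_sd=0.0))


@pytest.fixture
def tiny_ds():
    return make_dataset(
        [
            ("p1", "ACDEF", 3600.0),
            ("p2", "GGGGGG", 120.0),
            ("p3", "KLMNP", 40.0),
            ("p4", "WYVST", 7200.0),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
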