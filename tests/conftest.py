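import numpy as np
import pytest

from riboquant import (
    NoiseModel,
    default_probing_sites,
    titration_concentrations,
    random_construct,
    simulate_titration,
)


@pytest.fixture
def sites():
    return default_probing_sites()


@pytest.fixture
def noiseless_series(sites):
    """Titration generated exactly on the one-to-one isotherm, K_D 2.2 mM."""
    return simulate_titration(
        true_kd=2.2,
        sites=sites,
        concentrations=titration_concentrations(),
        noise=NoiseModel(cv=0.0, seed=0),
    )


@pytest.fixture
def tandem_construct():
    return random_construct(
        seed=42, init_len=14, elong_len=300, u_run=6, n_terminators=2
    )


@pytest.fixture
def single_construct():
    return random_construct(
        seed=7, init_len=13, elong_len=157, u_run=6, n_terminators=1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
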