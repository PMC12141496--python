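import pytest

from radscreen import SimParams, default_design, simulate_counts


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def small_sim(design):
    """A 300-gene default-condition simulation shared across tests."""
    return simulate_counts(design, SimParams(n_genes=300, seed=11))
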