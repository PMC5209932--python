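import pytest

from marketce import AnalysisConfig, croatia_gt1_inputs


@pytest.fixture(scope="session")
def croatia():
    """Built-in Croatian GT1 input set (therapies, population, config)."""
    return croatia_gt1_inputs()


@pytest.fixture(scope="session")
def therapies(croatia):
    return croatia[0]


@pytest.fixture(scope="session")
def population(croatia):
    return croatia[1]


@pytest.fixture(scope="session")
def new_entrant(therapies):
    return next(t for t in therapies if t.is_new_entrant)


@pytest.fixture()
def small_config():
    """A fast configuration for pipeline-shape tests."""
    return AnalysisConfig(n_runs=400, master_seed=7)
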