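import pytest

from apmscurate.curation import curate
from apmscurate.synthetic import SimulationConfig, generate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One default-parameter simulated experiment, shared across tests."""
    config = SimulationConfig(seed=7)
    table, design, truth = generate_experiment(config)
    return config, table, design, truth


@pytest.fixture(scope="session")
def default_curation(default_experiment):
    config, table, design, truth = default_experiment
    result = curate(table, design, contaminants=truth.contaminants)
    return result, truth


@pytest.fixture
def small_config():
    """A <=50-protein experiment for exhaustive oracle comparisons."""
    return SimulationConfig(
        n_true=12, n_background=30, frac_shared=0.5, mu_true=25.0,
        mu_background=8.0, suppression=0.1, dispersion=5.0,
        frac_contaminant=0.3, seed=11,
    )
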