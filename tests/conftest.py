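import pytest

from allelescan.pipeline import scan_population
from allelescan.simulate import SimConfig, plan_from_distribution, simulate_dataset


@pytest.fixture(scope="session")
def catalogue_config():
    """Default study conditions: 29 alleles carrying the published event plan."""
    return SimConfig(seed=1, event_plan=plan_from_distribution())


@pytest.fixture(scope="session")
def sim_dataset(catalogue_config):
    """(reference, model, allele records, truth) for the default population."""
    return simulate_dataset(catalogue_config)


@pytest.fixture(scope="session")
def population_scan(sim_dataset):
    reference, model, records, _ = sim_dataset
    return scan_population(records, reference, model)


@pytest.fixture(scope="session")
def reference(sim_dataset):
    return sim_dataset[0]


@pytest.fixture(scope="session")
def gene_model(sim_dataset):
    return sim_dataset[1]
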