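import warnings

import pytest

from streammox.landscape import community_landscape
from streammox.synth import gen_otu_table, gen_sites, simulate_incubation

SEED = 1


@pytest.fixture(scope="session")
def site_panel():
    """Default 14-site gradient panel with planted kinetic truth."""
    sites, truth = gen_sites(14, seed=SEED)
    return sites, truth


@pytest.fixture(scope="session")
def planted_table(site_panel):
    """OTU table with the planted 23 + 7 + 6 methanotroph structure."""
    sites, truth = site_panel
    table, truth = gen_otu_table(sites, n_otus=2000, seed=SEED, truth=truth)
    return table, truth


@pytest.fixture(scope="session")
def landscape_run(planted_table):
    table, truth = planted_table
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result, ordination = community_landscape(table, seed=SEED)
    return result, ordination, truth


@pytest.fixture(scope="session")
def noisefree_series():
    """One noise-free sediment incubation at V_max=10, K_S=3."""
    return simulate_incubation(10.0, 3.0, noise_cv=0.0, seed=SEED)
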