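import numpy as np
import pytest

from pqtlmap import assoc, simdata


@pytest.fixture(scope="session")
def small_panel():
    """72-strain, 600-marker structured panel shared across tests."""
    return simdata.simulate_panel(n_strains=72, n_markers=600, n_chrom=19, n_clusters=6, seed=11)


@pytest.fixture(scope="session")
def planted(small_panel):
    """Default three-hotspot architecture planted on the small panel."""
    abundance, annotation, truth = simdata.plant_architecture(small_panel, seed=11)
    return abundance, annotation, truth


@pytest.fixture(scope="session")
def small_kinship(small_panel):
    return assoc.compute_kinship(small_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
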