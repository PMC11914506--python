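import numpy as np
import pandas as pd
import pytest

from aneuadapt import synthetic_data as sd


@pytest.fixture(scope="session")
def catalog():
    return sd.make_genome(n_chromosomes=4, genes_per_arm=50, seed=7)


@pytest.fixture(scope="session")
def small_catalog():
    return sd.make_genome(n_chromosomes=2, genes_per_arm=10, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def cellline_sim(catalog):
    """One simulated proteome experiment shared by several tests."""
    config = sd.SimulationConfig(seed=7, compensation_factor=0.5,
                                 replicate_sd=0.1)
    karyotypes, parent_of = sd.default_cellline_design(catalog)
    return sd.simulate_cellline_proteomes(catalog, karyotypes, config,
                                          parent_of)
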