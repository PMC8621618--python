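import numpy as np
import pytest

from xfpclone import CloneCaller, SimulationConfig, annotate_barcodes, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """200-progenitor cohort at the default generative conditions."""
    config = SimulationConfig(n_progenitors=200, seed=0)
    cells, truth = generate_cohort(config)
    return config, cells, truth


@pytest.fixture(scope="session")
def default_called(default_cohort):
    """Barcoded cells + fitted CloneCaller on the default cohort."""
    _, cells, truth = default_cohort
    coded = annotate_barcodes(cells)
    caller = CloneCaller().fit(coded)
    return coded, truth, caller


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noise-free cohort: clone calling must be error-free on it."""
    config = SimulationConfig(n_progenitors=30, noise_sd=0.0, seed=5, n_sections=8)
    cells, truth = generate_cohort(config)
    return config, cells, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
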