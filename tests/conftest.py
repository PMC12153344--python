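import numpy as np
import pytest

from ppredit import synthetic_data as sd


@pytest.fixture(scope="session")
def factor():
    return sd.default_factor()


@pytest.fixture(scope="session")
def table():
    return sd.default_scoring_table()


@pytest.fixture(scope="session")
def fixture_matrix():
    return sd.transcribe_table2_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset(factor, table):
    """One RNA sample with 5 planted sites, no sequencing error."""
    cfg = sd.SimulationConfig(
        genome_length=2000,
        n_target_sites=1,
        n_decoy_sites=4,
        editing_fractions=(0.8, 0.05, 0.1, 0.2, 0.4),
        depth_mean=500,
        depth_dispersion=20,
        seq_error_rate=0.0,
        rng_seed=11,
    )
    return sd.simulate_dataset(cfg, factor, table, n_rna_samples=1, n_negative_controls=1)
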