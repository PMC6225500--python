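import pytest

from barcodekit import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 6-species dataset with clearly separated clusters."""
    params = SimulationParams(
        n_species=6,
        individuals_per_species=3,
        n_columns=400,
        intra_divergence=0.002,
        inter_divergence=0.05,
        n_diagnostic_sites_per_species=1,
        indel_column_rate=0.0,
        seed=11,
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default regime (12 species x 4, 680 columns)."""
    return simulate_dataset(SimulationParams(seed=0))
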