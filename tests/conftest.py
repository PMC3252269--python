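import pytest

from hgtsieve.pipeline import PipelineConfig, PipelineInputs, run_pipeline
from hgtsieve.simulate import (
    SPECIES_SUPERFAMILY,
    SimulationConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The default seeded simulation: 200 families, planted transfers."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline_result(default_dataset):
    ds = default_dataset
    inputs = PipelineInputs(
        ds.records,
        ds.species_info,
        ds.annotations,
        ds.families,
        species_superfamily=SPECIES_SUPERFAMILY,
    )
    return run_pipeline(PipelineConfig(seed=1), inputs)


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-family dataset for cheaper end-to-end checks."""
    return generate_dataset(SimulationConfig(seed=7, n_families=30))
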