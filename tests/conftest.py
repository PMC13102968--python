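import numpy as np
import pytest

from dnmpipe.bundle import simulate_cohort
from dnmpipe.config import ArtifactRates, FilterParams, SimulationConfig
from dnmpipe.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small but non-trivial cohort: 6 families, 4 Mbp genome, boosted rates
    so each child carries ~30 variants."""
    return SimulationConfig(
        n_families=6,
        quad_fraction=0.5,
        genome_length=2_000_000,
        n_chromosomes=2,
        germline_rate=3e-6,
        pzm_rate=6e-7,
        germline_indel_rate=3e-7,
        pzm_indel_rate=8e-8,
        panel_sites_per_child=500,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def clean_config(small_config) -> SimulationConfig:
    """Same cohort without injected artifacts (for sensitivity checks)."""
    return small_config.evolve(artifact_rates=ArtifactRates(0.0, 0.0), seed=12)


@pytest.fixture(scope="session")
def clean_bundle(clean_config):
    return simulate_cohort(clean_config)


@pytest.fixture(scope="session")
def pipeline_result(small_bundle):
    return run_pipeline(small_bundle, FilterParams())


@pytest.fixture(scope="session")
def clean_result(clean_bundle):
    return run_pipeline(clean_bundle, FilterParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
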