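import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160919)


@pytest.fixture(scope="session")
def demo_sim():
    """One small simulated study shared across tests (read-only)."""
    from tedyn import synthetic_data as sd

    config = sd.SimulationConfig(seed=42, reads_per_accession=500, n_loci=150)
    specs = sd.default_family_specs(config.accessions)
    return sd.simulate_genome(specs, config), specs, config
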