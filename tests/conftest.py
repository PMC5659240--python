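import pytest
from hypothesis import HealthCheck, settings

from tutag import SimulationConfig, generate_catalog, simulate_counts

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated experiment shared by read-only tests."""
    cfg = SimulationConfig(n_genes=600, seed=7)
    catalog = generate_catalog(cfg)
    matrix, sheet, truth = simulate_counts(catalog, cfg)
    return cfg, catalog, matrix, sheet, truth
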