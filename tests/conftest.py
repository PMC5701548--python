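import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_sim():
    """Small clean (noise-free) simulation shared across tests."""
    from transcurate.simulate import SimParams, simulate
    params = SimParams(n_genes=12, snp_rate=0.0, indel_rate=0.0,
                       fragmentation=0.0, n_contaminants=5, seed=42)
    return simulate(params)
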