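import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """A modest neutral panel reused across tests (600 SNPs, default 52/21 layout)."""
    from geascan import SimConfig, simulate_panel

    return simulate_panel(SimConfig(n_snps=600, seed=7))


@pytest.fixture(scope="session")
def spiked_sim():
    """A panel with spiked environment-associated SNPs."""
    from geascan import SimConfig, simulate_panel

    return simulate_panel(SimConfig(n_snps=2000, beta=0.2, frac_selected=0.01, seed=11))
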