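import pytest
from hypothesis import settings

from condqtl import SimConfig, simulate_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def study(default_cfg):
    """One default synthetic study shared by read-only tests."""
    return simulate_study(default_cfg)
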