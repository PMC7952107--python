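import numpy as np
import pytest

from edflow.config import builtin_config, default_pathway_specs
from edflow.distributions import ArrivalProfile, ServiceDistributionSpec
from edflow.ed_model import PROCESS_NAMES, PathwayConfig, ResourceConfig


@pytest.fixture(scope="session")
def shipped_config():
    """The calibrated defaults shipped with the package."""
    return builtin_config()


@pytest.fixture(scope="session")
def table_specs():
    """The eleven shipped process-duration distribution specs."""
    return default_pathway_specs()


def constant_pathway(p_test_esi4=0.0, p_test_esi5=0.0, **overrides):
    """Pathway where every process is constant (default 0 minutes)."""
    specs = {n: ServiceDistributionSpec("constant", 0.0) for n in PROCESS_NAMES}
    for name, minutes in overrides.items():
        specs[name] = ServiceDistributionSpec("constant", float(minutes))
    return PathwayConfig(specs, p_test_esi4, p_test_esi5)


@pytest.fixture
def ample_resources():
    """Effectively unconstrained resources: no queueing anywhere."""
    return ResourceConfig(n_rooms=10_000, n_nurses=10_000, n_providers=10_000)


def flat_profile(rate_per_hour: float, esi4_fraction: float = 0.8) -> ArrivalProfile:
    return ArrivalProfile(
        hourly_rates=(float(rate_per_hour),) * 24, esi4_fraction=esi4_fraction
    )
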