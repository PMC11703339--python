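import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from twinclock import (StructuralParams, default_config, recovery_config,
                       simulate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A paper-scale cohort with singletons (186 families)."""
    return simulate_cohort(default_config(rng_seed=11))


@pytest.fixture(scope="session")
def paired_cohort():
    """A moderate complete-pair cohort on the rescaled analysis metric."""
    return simulate_cohort(recovery_config(400, 400, rng_seed=21))


def ace_structural(va, vc, ve, **kw):
    """Pure-ACE childhood-IQ phenotype with no SES or downstream effects."""
    return StructuralParams(va_x=va, vc_x=vc, ve_x=ve, **kw)
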