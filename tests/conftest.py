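import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lipidmr import SimConfig, harmonize, simulate_triplet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def triplet():
    """A strong-instrument exposure/mediator/outcome triplet with truth."""
    cfg = SimConfig(n_snps=50, theta_total=0.2, seed=11)
    return simulate_triplet(cfg)


@pytest.fixture(scope="session")
def hset(triplet):
    exposure, _, outcome, _ = triplet
    return harmonize(exposure, outcome)
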