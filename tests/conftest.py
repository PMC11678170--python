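"""Shared fixtures and a deterministic hypothesis profile."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sckmipd.population import default_population

settings.register_profile(
    "det",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def pop():
    return default_population()


@pytest.fixture(scope="session")
def typical_pk(pop):
    return pop.pk_typical


@pytest.fixture(scope="session")
def typical_pd(pop):
    """Typical PD parameters at a representative baseline."""
    from dataclasses import replace

    return replace(pop.pd_typical, PASI_base=11.6)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
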