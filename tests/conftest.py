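import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from biofilmsim import engine
from biofilmsim.domain import DomainGrid
from biofilmsim.params import lactobacillus_paracasei, streptococcus_oralis

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def so():
    return streptococcus_oralis()


@pytest.fixture
def lb():
    return lactobacillus_paracasei()


@pytest.fixture
def small_grid():
    """Desk-scale domain for fast integration tests."""
    return DomainGrid(64.0, 64.0, 48.0, 8.0, boundary_layer_thickness=24.0)


def fast_config(variant="competition", seed_counts=None, grid=None,
                **overrides):
    """A quick-running configuration for integration tests: small domain,
    short duration, coarse step."""
    kw = dict(
        variant=variant,
        seed_counts=seed_counts or {"so34": 16, "lb334": 16},
        grid=grid or DomainGrid(64.0, 64.0, 48.0, 8.0,
                                boundary_layer_thickness=24.0),
        duration=2.0,
        dt=0.1,
        output_interval=1.0,
        replicates=2,
    )
    kw.update(overrides)
    return engine.RunConfig(**kw)


@pytest.fixture
def quick_config():
    return fast_config()


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(42))
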