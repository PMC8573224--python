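import pytest
from hypothesis import HealthCheck, settings

import batmoma as bm

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def core_model():
    """Textbook E. coli core model under glucose 10 / ATPM 7.6, aerobic."""
    return bm.apply_medium(bm.load_ecoli_core(), bm.MediumSpec())


@pytest.fixture(scope="session")
def core_reference(core_model):
    return bm.reference_flux(core_model)


@pytest.fixture
def toy():
    """Two-branch toy network (11 reactions, 5 knockable units)."""
    return bm.make_toy_model(2, seed=1)


@pytest.fixture
def toy3():
    return bm.make_toy_model(3, seed=2)
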