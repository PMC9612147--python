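import pytest
from hypothesis import HealthCheck, settings

from mtmarker import simkit
from mtmarker.seqcore import Interval

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_reference():
    """A 5-kb circular reference, enough structure for fast panel tests."""
    return simkit.simulate_reference(5000, 0.25, seed=42)


@pytest.fixture(scope="session")
def small_panel(small_reference):
    """Strain panel on the small reference: planted window 1000-1399."""
    spec = simkit.PanelSpec(
        genome_length=5000,
        planted_window=Interval(1000, 1399),
        seed=42,
    )
    strains, truth = simkit.simulate_strains(small_reference, spec)
    return spec, strains, truth


@pytest.fixture(scope="session")
def default_reference():
    """Full-scale reference: 35 kb circular, 24.3% GC."""
    return simkit.simulate_reference(35_000, 0.243, seed=7)


@pytest.fixture(scope="session")
def default_panel(default_reference):
    spec = simkit.PanelSpec(seed=7)
    strains, truth = simkit.simulate_strains(default_reference, spec)
    return spec, strains, truth
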