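import pytest
from hypothesis import settings

from equidea.synthetic import FrontierSpec, PanelSpec, gen_frontier_panel, gen_panel

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    """Default synthetic 31-DMU x 5-year grouped log-normal panel."""
    return gen_panel(PanelSpec(seed=42))


@pytest.fixture(scope="session")
def small_panel():
    """3-group, 6-DMU, 2-year panel for fast exact checks."""
    spec = PanelSpec(group_sizes={"eastern": 2, "middle": 2, "western": 2},
                     years=(2013, 2014), seed=7)
    return gen_panel(spec)


@pytest.fixture(scope="session")
def frontier():
    """Noise-free constructed-frontier panel with its truth table."""
    spec = FrontierSpec(seed=11, years=(2013, 2014, 2015))
    return gen_frontier_panel(spec)
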