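import pytest
from hypothesis import settings

import dopagrs as d

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def hs5() -> d.ScorePanel:
    """The shipped 5-variant dopamine panel (scores 0-10)."""
    return d.builtin_panel("hs5")


@pytest.fixture(scope="session")
def sim_cohort(hs5) -> d.CohortTable:
    """A complete synthetic discovery-style cohort (n = 273, seed fixed)."""
    spec = d.SimulationSpec(seed=123)
    return d.simulate_cohort(spec, hs5, with_dosages=True)
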