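import pytest

from ksdcohort.panel import default_panel
from ksdcohort.simulate import SimConfig, generate_genotypes


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (701 stone formers, 200 controls)."""
    return generate_genotypes(SimConfig(seed=1))
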