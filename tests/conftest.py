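import numpy as np
import pytest

import nutristage as ns
from nutristage.core import SESGroup
from nutristage.synthetic import synthetic_demography


@pytest.fixture(scope="session")
def demo_pop():
    """Shared synthetic demography + population pyramid."""
    return synthetic_demography()


@pytest.fixture(scope="session")
def paper_like_waves():
    """One seeded noiseless scenario with survey-like rate magnitudes."""
    scn = ns.generate_truth(7, "paper_like")
    waves = ns.generate_waves(scn)
    w1, w2 = waves[SESGroup.ALL]
    return scn, w1, w2


@pytest.fixture
def uniform_initial(demo_pop):
    """Initial state: every group 1000 people split 70/20/10."""
    demo, _ = demo_pop
    stocks = np.tile(np.array([700.0, 200.0, 100.0]), (12, 1))
    return ns.PopulationState(t=2005.0, stocks=stocks), demo
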