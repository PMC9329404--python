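import numpy as np
import pytest

import stratamr as smr


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def a2_cohort():
    """One fixed Scenario-A2 cohort reused across estimator tests."""
    params = smr.build_scenario("A2", {"mu1": -1.0, "mu2": -1.0})
    return smr.simulate_cohort(params, 42)
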