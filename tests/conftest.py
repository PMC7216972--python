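import numpy as np
import pytest
from hypothesis import settings

import redfac as rf

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Weibull rates calibrated so S(2.5) = 0.05 for shapes 0.5 / 1 / 2
RATES = {b: rf.solve_rate_for_survival(b, 2.5, 0.05) for b in (0.5, 1.0, 2.0)}


@pytest.fixture(scope="session")
def toy():
    """4-subject hand-checkable fixture: times 1..4, statuses (1,2,1,1)."""
    return rf.toy_dataset()


@pytest.fixture(scope="session")
def middle_middle():
    """Constant-hazard cause pair with covariate effects on both causes."""
    return rf.TwoCauseModel(rf.WeibullHazard(RATES[1.0], 1.0),
                            rf.WeibullHazard(RATES[1.0], 1.0),
                            beta1=0.5, beta2=0.25)


def simulate_study(model, n=200, seed=0, censoring=("admin", 0.6)):
    """One dataset under the standard study conditions (binary x, p=0.5)."""
    return rf.simulate_competing_risks(
        rf.SimulationDesign(n=n, model=model, covariate_p=0.5,
                            censoring=censoring, seed=seed))


@pytest.fixture(scope="session")
def censored_study(middle_middle):
    """Moderately censored dataset used across regression tests."""
    return simulate_study(middle_middle, n=400, seed=11,
                          censoring=("uniform+admin", 1.8, 0.6))
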