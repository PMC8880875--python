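import numpy as np
import pytest

import mdma_cea as m


@pytest.fixture(scope="session")
def base():
    """The default parameter set with the bundled synthetic life table."""
    return m.base_case()


@pytest.fixture(scope="session")
def traces(base):
    """Both arms' 30-year traces under the default conventions."""
    tm = m.run_cohort(base, m.mdma_arm(base))
    tc = m.run_cohort(base, m.control_arm(base))
    return tm, tc


@pytest.fixture
def flat_mortality_params(base):
    """Base case with (numerically) negligible mortality and a single age stratum.

    Lets utility/cost accounting be checked in isolation from deaths.
    """
    lt = m.LifeTable(ages=np.arange(0, 121.0), qx=np.full(121, 1e-12))
    return base.replace(life_table=lt, age_sd=0.0)
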