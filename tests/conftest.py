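import numpy as np
import pytest

import microage as ma


@pytest.fixture(scope="session")
def small_cohort() -> ma.GeneratedCohort:
    """Down-scaled longitudinal cohort shared across tests (seed fixed)."""
    return ma.simulate_cohort(ma.small_design(seed=7))


@pytest.fixture()
def toy_table() -> ma.CountTable:
    return ma.CountTable(["tA", "tB"], ["s1", "s2"],
                         np.array([[5, 0], [1, 2]]))
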