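import numpy as np
import pandas as pd
import pytest

from bmicohort.datasets import load_child_cutoffs, load_hazard_ratios
from bmicohort.mortality import HazardRatioTable, LifeTable
from bmicohort.survival import TransitionSchedule, build_schedule, load_default_models
from bmicohort.synthetic import calibrate_life_table


@pytest.fixture(scope="session")
def cutoffs():
    return load_child_cutoffs()


@pytest.fixture(scope="session")
def default_models():
    return load_default_models()


@pytest.fixture(scope="session")
def schedule(default_models):
    return build_schedule(default_models)


@pytest.fixture(scope="session")
def lifetable():
    return calibrate_life_table()


@pytest.fixture(scope="session")
def hr_table():
    return load_hazard_ratios()


@pytest.fixture(scope="session")
def hr_neutral():
    return HazardRatioTable.all_ones()


@pytest.fixture
def flat_lifetable():
    """Flat mortality rate fixture (for closed-form checks)."""
    def make(rate: float) -> LifeTable:
        rows = [(sex, a, rate) for sex in ("female", "male") for a in range(0, 101)]
        return LifeTable(pd.DataFrame(rows, columns=["sex", "age", "rate"]))
    return make


@pytest.fixture
def zero_schedule():
    """Schedule with all transition probabilities zero."""
    ages = TransitionSchedule.AGES
    probs = {(sex, aid): np.zeros(len(ages))
             for sex in ("female", "male") for aid in range(1, 7)}
    return TransitionSchedule(probs)
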