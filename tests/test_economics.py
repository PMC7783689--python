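"""Two-part cost model, cost schedules and discounted accumulation."""

import numpy as np
import pandas as pd
import pytest

from bmicohort.economics import (
    CostSchedule,
    TwoPartCostModel,
    expected_costs,
    extend_cost_schedule,
    fit_two_part,
    marginal_incremental_cost,
)
from bmicohort.engine import CohortTrace, S
from bmicohort.states import ConfigurationError, HealthState
from bmicohort.survival import EstimationError
from bmicohort.synthetic import simulate_cost_records


@pytest.fixture(scope="module")
def cost_fixture():
    return simulate_cost_records(20_000, seed=11)


@pytest.fixture(scope="module")
def fitted(cost_fixture):
    return fit_two_part(cost_fixture, "female")


class TestTwoPart:
    def test_requires_both_zero_and_positive(self, cost_fixture):
        allpos = cost_fixture.assign(annual_cost=cost_fixture.annual_cost + 1.0)
        with pytest.raises(EstimationError):
            TwoPartCostModel.from_dataframe(allpos, "female").fit()
        allzero = cost_fixture.assign(annual_cost=0.0)
        with pytest.raises(EstimationError):
            TwoPartCostModel.from_dataframe(allzero, "female").fit()

    def test_positive_part_reproduces_sample_mean(self, cost_fixture, fitted):
        """Gamma GLM with log link: fitted mean of positives ≈ sample mean."""
        sub = cost_fixture[(cost_fixture.sex == "female") & (cost_fixture.annual_cost > 0)]
        pred = fitted.part2.predict(
            __import__("bmicohort.economics", fromlist=["_design"])._design(sub)
        )
        assert np.mean(pred) == pytest.approx(sub.annual_cost.mean(), rel=0.01)

    def test_class_effect_recovery(self, cost_fixture, fitted):
        """The generator's OB1-vs-NW cost gap is recovered by the AME."""
        ame = fitted.incremental_cost("OB1", 50)
        # truth at age 50: participation 0.63*2000 - 0.55*1400 = 490
        truth = 0.63 * 2000 - 0.55 * 1400
        assert ame == pytest.approx(truth, rel=0.2)

    def test_nw_increment_is_zero(self, fitted):
        assert marginal_incremental_cost(fitted, "female", 40, "NW") == 0.0

    def test_age_outside_range_rejected(self, fitted):
        with pytest.raises(ConfigurationError):
            marginal_incremental_cost(fitted, "female", 85, "OB1")

    def test_null_class_effect_recovered_as_zero(self):
        """With no class effects in truth, increments are ~0."""
        rec = simulate_cost_records(
            20_000, seed=3,
            participation={c: 0.6 for c in ("NW", "OW", "OB1", "OB2")},
            mean_cost={c: 1500.0 for c in ("NW", "OW", "OB1", "OB2")},
        )
        res = fit_two_part(rec, "male")
        ame = res.incremental_cost("OB2", 50)
        assert abs(ame) < 120  # Monte-Carlo tolerance around zero


class TestSchedule:
    def test_flat_table_extension_rules(self):
        tab = pd.DataFrame({
            "sex": ["female"] * 3, "state": ["OW", "OB1", "OB2"],
            "ame_eur": [160.0, 631.0, 698.0],
        })
        sched = extend_cost_schedule(tab, under20_rule="zero", sexes=("female",))
        assert sched.increment("female", "OB1", 95) == sched.increment("female", "OB1", 80)
        assert sched.increment("female", "OB1", 10) == 0.0
        assert sched.increment("female", "NW", 50) == 0.0
        sched2 = extend_cost_schedule(tab, under20_rule="constant_at_20", sexes=("female",))
        assert sched2.increment("female", "OW", 10) == sched2.increment("female", "OW", 20)

    def test_nw1_nw2_share_zero_increment(self):
        tab = pd.DataFrame({"sex": ["male"] * 3, "state": ["OW", "OB1", "OB2"],
                            "ame_eur": [-96.0, 182.0, 1456.0]})
        sched = extend_cost_schedule(tab, sexes=("male",))
        assert sched.increment("male", HealthState.NW1, 50) == 0.0
        assert sched.increment("male", HealthState.NW2, 50) == 0.0
        # negative increments (men OW) are preserved as-is
        assert sched.increment("male", "OW", 50) == -96.0

    def test_unknown_rule_rejected(self):
        with pytest.raises(ConfigurationError):
            extend_cost_schedule(pd.DataFrame(), under20_rule="extrapolate")


def toy_trace(n_ob1=100.0, n_ages=3, start_age=2, total=200.0):
    persons = np.zeros((6, n_ages))
    persons[S[HealthState.OB1], :] = n_ob1
    persons[S[HealthState.NW1], :] = total - n_ob1
    return CohortTrace(sex="female", start_age=start_age, persons=persons)


def toy_schedule(increment=10.0):
    rows = [("female", s, a, increment if s == "OB1" else 0.0)
            for s in ("OW", "OB1", "OB2", "NW") for a in range(2, 101)]
    return CostSchedule(pd.DataFrame(rows, columns=["sex", "state", "age",
                                                    "incremental_cost_eur"]))


class TestExpectedCosts:
    def test_zero_schedule_zero_costs(self):
        cs = expected_costs(toy_trace(), toy_schedule(0.0), 0.04)
        assert cs.total == 0.0 and cs.total_discounted == 0.0

    def test_hand_arithmetic_undiscounted(self):
        """100 OB1 persons, 3 cycles, €10: cumulative €3000, €15 per person."""
        cs = expected_costs(toy_trace(), toy_schedule(10.0), discount_rate=0.0)
        assert cs.total == pytest.approx(3000.0)
        assert cs.total_per_person == pytest.approx(15.0)

    def test_closed_form_discounting(self):
        cs = expected_costs(toy_trace(), toy_schedule(10.0), discount_rate=0.04)
        expected = 1000.0 * (1 + 1 / 1.04 + 1 / 1.04**2)
        assert cs.total_discounted == pytest.approx(expected, abs=1e-9)

    def test_discounted_below_undiscounted(self, schedule, lifetable, hr_table):
        from bmicohort.engine import ModelSpec, run_cohort
        trace = run_cohort(ModelSpec(), schedule, lifetable, hr_table, "female")
        tab = pd.DataFrame({"sex": ["female"] * 3, "state": ["OW", "OB1", "OB2"],
                            "ame_eur": [160.0, 631.0, 698.0]})
        cs = expected_costs(trace, extend_cost_schedule(tab, sexes=("female",)), 0.04)
        assert cs.total_discounted < cs.total
        # occupancy-weighted identity: annual per-person equals the
        # occupancy-weighted mean of per-state increments
        age = 50
        k = age - trace.start_age
        manual = sum(
            trace.occupancy(HealthState(s))[k] * (160.0 if s == "OW" else
                                                  631.0 if s == "OB1" else 698.0)
            for s in ("OW", "OB1", "OB2")
        )
        assert cs.annual[k] == pytest.approx(manual, rel=1e-12)

    def test_survival_adjustment_monotone(self, schedule, lifetable, hr_table):
        """Higher mortality reduces late-life cumulative incremental costs."""
        from bmicohort.engine import ModelSpec, run_cohort
        from bmicohort.mortality import LifeTable
        spec = ModelSpec()
        tab = pd.DataFrame({"sex": ["female"] * 3, "state": ["OW", "OB1", "OB2"],
                            "ame_eur": [160.0, 631.0, 698.0]})
        sched = extend_cost_schedule(tab, sexes=("female",))
        base = expected_costs(run_cohort(spec, schedule, lifetable, hr_table,
                                         "female"), sched, 0.0)
        inflated = LifeTable(lifetable.frame.assign(rate=lifetable.frame.rate * 2))
        high = expected_costs(run_cohort(spec, schedule, inflated, hr_table,
                                         "female"), sched, 0.0)
        assert high.total < base.total
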