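"""Markov cohort engine: matrices, traces, prevalence, life expectancy."""

import numpy as np
import pandas as pd
import pytest

from bmicohort.engine import (
    CohortModel,
    ModelSpec,
    S,
    assemble_matrix,
    compare_prevalence,
    life_expectancy,
    microsimulate,
    prevalence_among_alive,
    run_cohort,
)
from bmicohort.states import ConfigurationError, HealthState


@pytest.fixture(scope="module")
def spec():
    return ModelSpec()


class TestMatrix:
    def test_identity_with_zero_inputs(self, zero_schedule, flat_lifetable, hr_neutral):
        P = assemble_matrix(50, "female", zero_schedule, flat_lifetable(0.0), hr_neutral)
        assert np.allclose(P, np.eye(6))

    def test_rows_sum_to_one(self, schedule, lifetable, hr_table):
        for age in (2, 12, 13, 19, 20, 55, 99):
            for sex in ("female", "male"):
                P = assemble_matrix(age, sex, schedule, lifetable, hr_table)
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(P >= 0)

    def test_ow_row_arrow_set(self, schedule, lifetable, hr_table):
        """OW can only stay, progress to OB1, regress to NW2, or die."""
        P = assemble_matrix(30, "male", schedule, lifetable, hr_table)
        ow = S[HealthState.OW]
        allowed = {S[HealthState.OW], S[HealthState.OB1],
                   S[HealthState.NW2], S[HealthState.DEAD]}
        nonzero = set(np.flatnonzero(P[ow] > 0))
        assert nonzero <= allowed
        # NW1 never receives regressing mass
        assert P[ow, S[HealthState.NW1]] == 0.0

    def test_dead_absorbing(self, schedule, lifetable, hr_table):
        P = assemble_matrix(40, "female", schedule, lifetable, hr_table)
        dead = S[HealthState.DEAD]
        assert P[dead, dead] == 1.0


class TestCohortRun:
    def test_conservation_and_monotone_dead(self, spec, schedule, lifetable, hr_table):
        trace = run_cohort(spec, schedule, lifetable, hr_table, "female")
        totals = trace.persons.sum(axis=0)
        assert np.allclose(totals, spec.cohort_female, rtol=1e-9)
        dead = trace.occupancy(HealthState.DEAD)
        assert np.all(np.diff(dead) >= -1e-9)
        assert np.all(trace.persons >= -1e-9)

    def test_constant_occupancy_without_dynamics(self, spec, zero_schedule,
                                                 flat_lifetable, hr_neutral):
        trace = run_cohort(spec, zero_schedule, flat_lifetable(0.0), hr_neutral, "male")
        for k in range(trace.persons.shape[1]):
            assert np.allclose(trace.persons[:, k], trace.persons[:, 0])

    def test_initial_distribution_assignment(self, spec, schedule, lifetable, hr_table):
        trace = run_cohort(spec, schedule, lifetable, hr_table, "female")
        p0 = trace.persons[:, 0] / spec.cohort_female
        assert p0[S[HealthState.NW1]] == pytest.approx(0.8983)
        assert p0[S[HealthState.NW2]] == 0.0
        assert p0[S[HealthState.OB2]] == pytest.approx(0.0033)

    def test_mortality_neutrality_with_unit_hazards(self, spec, schedule,
                                                    lifetable, hr_neutral):
        """With all HRs = 1 engine survivorship telescopes to the life table's."""
        trace = run_cohort(spec, schedule, lifetable, hr_neutral, "female")
        m = lifetable.rates("female")[:-1]  # ages 2..99
        expected = np.concatenate([[1.0], np.cumprod(np.exp(-m))])
        assert np.allclose(trace.alive_fraction(), expected, atol=1e-12)

    def test_matches_microsimulation_oracle(self, spec, schedule, lifetable, hr_table):
        """Deterministic occupancies sit within 3 MC s.e. of a 200k-agent run."""
        n_agents = 200_000
        micro = microsimulate(spec, schedule, lifetable, hr_table, "female",
                              n_agents=n_agents, seed=123)
        det = run_cohort(spec, schedule, lifetable, hr_table, "female")
        frac_det = det.persons / det.cohort_size
        frac_mc = micro.persons / micro.cohort_size
        se = np.sqrt(np.maximum(frac_det * (1 - frac_det), 1e-12) / n_agents)
        # allow a tiny absolute floor for near-degenerate cells
        assert np.all(np.abs(frac_mc - frac_det) <= 3 * se + 1e-4)


class TestPrevalence:
    def test_initial_prevalence(self, spec, schedule, lifetable, hr_table):
        trace = run_cohort(spec, schedule, lifetable, hr_table, "male")
        prev = prevalence_among_alive(trace, 2)
        assert prev["NW"] == pytest.approx(0.8983)
        assert prev["OW"] == pytest.approx(0.0898)
        assert prev["OB1"] == pytest.approx(0.0086)
        assert prev["OB2"] == pytest.approx(0.0033)

    def test_fractions_sum_to_one(self, spec, schedule, lifetable, hr_table):
        trace = run_cohort(spec, schedule, lifetable, hr_table, "female")
        for age in (2, 30, 60, 90, 100):
            assert sum(prevalence_among_alive(trace, age).values()) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_compare_prevalence_multinomial_self_consistency(
            self, spec, schedule, lifetable, hr_table):
        """References sampled from the model's own multinomial at n = 5000
        per band fall within 95% sampling bounds in ≥ 90% of band-replicates."""
        trace = run_cohort(spec, schedule, lifetable, hr_table, "male")
        rng = np.random.default_rng(77)
        n = 5000
        ages = [20, 30, 40, 50, 60, 70]
        hits = total = 0
        for _ in range(20):
            rows = []
            for age in ages:
                p = prevalence_among_alive(trace, age)["OW"]
                obs = rng.binomial(n, p) / n
                half = 1.959964 * np.sqrt(p * (1 - p) / n)
                rows.append((age, "OW", obs, p - half, p + half))
            ref = pd.DataFrame(rows, columns=["age", "weight_class", "observed",
                                              "cb_lo", "cb_hi"])
            out = compare_prevalence(trace, ref)
            hits += out.within_cb.sum()
            total += len(out)
        assert hits / total >= 0.90

    def test_compare_prevalence_self_reference(self, spec, schedule, lifetable, hr_table):
        trace = run_cohort(spec, schedule, lifetable, hr_table, "female")
        ref = pd.DataFrame({
            "age": [30, 50], "weight_class": ["OW", "OB1"],
            "observed": [prevalence_among_alive(trace, 30)["OW"],
                         prevalence_among_alive(trace, 50)["OB1"]],
        })
        out = compare_prevalence(trace, ref)
        assert np.allclose(out.difference, 0.0, atol=1e-12)


class TestLifeExpectancy:
    def test_zero_mortality_truncates_at_horizon(self, spec, zero_schedule,
                                                 flat_lifetable, hr_neutral):
        trace = run_cohort(spec, zero_schedule, flat_lifetable(0.0), hr_neutral, "female")
        assert life_expectancy(trace) == pytest.approx(100.0)

    def test_flat_hazard_geometric_series(self, spec, zero_schedule,
                                          flat_lifetable, hr_neutral):
        """q = 1 - 0.9 per year: LE - 2 = sum of 0.9^t, t = 1..98."""
        rate = -np.log(0.9)
        trace = run_cohort(spec, zero_schedule, flat_lifetable(rate), hr_neutral, "male")
        expected = 2 + sum(0.9**t for t in range(1, 99))
        assert life_expectancy(trace) == pytest.approx(expected, rel=1e-12)

    def test_cohort_model_wrapper(self, spec, schedule, lifetable, hr_table):
        model = CohortModel(spec, schedule, lifetable, hr_table)
        both = model.run_both()
        le_f = life_expectancy(both["female"])
        le_m = life_expectancy(both["male"])
        assert 70 < le_m < le_f < 95  # male rates are higher in the fixture


class TestSpecValidation:
    def test_initial_distribution_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(initial_distribution=(0.5, 0.2, 0.2, 0.2))

    def test_sex_sizes_must_sum(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(cohort_female=100, cohort_male=100)
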