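"""Scenario analyses: obesity elimination and conditional life expectancy.

Scenario 1 zeroes the OB1→OB2 transition (no one becomes grade-2 obese) and
reassigns the initial OB2 mass to OB1; scenario 2 zeroes OW→OB1 and
reassigns the initial OB1 + OB2 mass to OW.  The stay-probability absorbs
the removed transition mass, so transition-matrix rows still sum to one.
Scenarios 3–6 start the whole cohort at age 30 in a single weight class
(NW, OW, OB1, OB2) with standard dynamics thereafter; years of life lost
(YLL) is the life-expectancy difference vs the NW start, reported as
positive years lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import CohortTrace, ModelSpec, life_expectancy, run_cohort
from .mortality import HazardRatioTable, LifeTable
from .states import ConfigurationError, HealthState
from .survival import TRANSITION_LABELS, TransitionSchedule

__all__ = [
    "ScenarioSpec",
    "ELIMINATE_OB2",
    "ELIMINATE_OB",
    "apply_elimination",
    "conditional_life_expectancy",
    "yll_summary",
    "run_scenario",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the six scenario analyses.

    ``kind="eliminate"`` zeroes ``eliminate_analysis`` at every age and
    moves initial mass per ``reassign`` (a {from_index: to_index} map over
    the NW/OW/OB1/OB2 initial-distribution slots).  ``kind=
    "conditional_start"`` starts everyone at ``start_age`` in
    ``start_state``.
    """

    name: str
    kind: str  # "eliminate" | "conditional_start"
    eliminate_analysis: int | None = None
    reassign: tuple = ()
    start_age: int = 30
    start_state: HealthState | None = None


#: Scenario 1: no progression into grade-2 obesity.
ELIMINATE_OB2 = ScenarioSpec("s1", "eliminate", eliminate_analysis=3,
                             reassign=((3, 2),))
#: Scenario 2: no progression into obesity at all (initial OB1+OB2 -> OW).
ELIMINATE_OB = ScenarioSpec("s2", "eliminate", eliminate_analysis=2,
                            reassign=((2, 1), (3, 1)))

CONDITIONAL = {
    "s3": ScenarioSpec("s3", "conditional_start", start_state=HealthState.NW1),
    "s4": ScenarioSpec("s4", "conditional_start", start_state=HealthState.OW),
    "s5": ScenarioSpec("s5", "conditional_start", start_state=HealthState.OB1),
    "s6": ScenarioSpec("s6", "conditional_start", start_state=HealthState.OB2),
}
ALL_SCENARIOS = {"s1": ELIMINATE_OB2, "s2": ELIMINATE_OB, **CONDITIONAL}


def apply_elimination(
    schedule: TransitionSchedule, spec: ScenarioSpec, initial_distribution: tuple
) -> tuple[TransitionSchedule, tuple]:
    """Zero the target transition and reassign the initial distribution.

    Returns (modified schedule, modified initial distribution).  Total
    cohort mass is preserved by construction.
    """
    if spec.kind != "eliminate":
        raise ConfigurationError(f"scenario {spec.name} is not an elimination scenario")
    aid = spec.eliminate_analysis
    if aid not in TRANSITION_LABELS:
        raise ConfigurationError(f"unknown transition analysis {aid}")
    probs = {k: v.copy() for k, v in schedule.probs.items()}
    for (sex, a) in list(probs):
        if a == aid:
            probs[(sex, a)] = np.zeros_like(probs[(sex, a)])
    dist = list(initial_distribution)
    for frm, to in spec.reassign:
        dist[to] += dist[frm]
        dist[frm] = 0.0
    return TransitionSchedule(probs, dict(schedule.provenance)), tuple(dist)


def run_scenario(
    spec: ScenarioSpec,
    model_spec: ModelSpec,
    schedule: TransitionSchedule,
    lifetable: LifeTable,
    hrs: HazardRatioTable,
    sex: str,
) -> CohortTrace:
    """Run one scenario arm and return its cohort trace."""
    if spec.kind == "eliminate":
        sched2, dist2 = apply_elimination(schedule, spec, model_spec.initial_distribution)
        return run_cohort(model_spec, sched2, lifetable, hrs, sex,
                          initial_distribution=dist2)
    if spec.kind == "conditional_start":
        return run_cohort(model_spec, schedule, lifetable, hrs, sex,
                          start_age=spec.start_age, initial_state=spec.start_state)
    raise ConfigurationError(f"unknown scenario kind {spec.kind!r}")


def conditional_life_expectancy(
    start_state,
    model_spec: ModelSpec,
    schedule: TransitionSchedule,
    lifetable: LifeTable,
    hrs: HazardRatioTable,
    sex: str,
    start_age: int = 30,
) -> float:
    """Life expectancy of a cohort entirely in ``start_state`` at ``start_age``."""
    trace = run_cohort(model_spec, schedule, lifetable, hrs, sex,
                       start_age=start_age, initial_state=HealthState(start_state))
    return life_expectancy(trace, model_spec.half_cycle_correction)


def yll_summary(base: CohortTrace, scenario: CohortTrace,
                half_cycle_correction: bool = False) -> dict:
    """Per-person and whole-cohort years of life lost.

    Per-person YLL = LE(scenario) − LE(base), positive when the scenario
    (e.g. elimination of obesity) extends life; the cohort total multiplies
    by the arm's cohort size.
    """
    if base.sex != scenario.sex or base.start_age != scenario.start_age:
        raise ConfigurationError("base and scenario traces must match in sex and start age")
    if abs(base.cohort_size - scenario.cohort_size) > 1e-6:
        raise ConfigurationError("base and scenario traces must share cohort size")
    le_base = life_expectancy(base, half_cycle_correction)
    le_scen = life_expectancy(scenario, half_cycle_correction)
    per_person = le_scen - le_base
    return {
        "sex": base.sex,
        "le_base": le_base,
        "le_scenario": le_scen,
        "yll_per_person": per_person,
        "yll_total": per_person * base.cohort_size,
    }
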