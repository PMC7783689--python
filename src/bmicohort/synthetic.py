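"""Synthetic data generation with known ground truth.

Everything the model consumes can be generated here: longitudinal
height/weight cohorts whose latent annual weight-class paths follow known
parametric transition hazards, Gompertz–Makeham life tables, and
individual-level cost records from a known two-part process.  Generated
cohorts emulate the structure of linked health-survey data: near-annual
visits in childhood, multi-year gaps (≈ 4–11 y) in adolescence and
adulthood, an average of about 2.8 observations per person, and
non-informative dropout.

BMI values are drawn uniformly inside the class band implied by the latent
class at each visit age (the model works on class dynamics, not continuous
BMI); heights follow a deterministic sex-specific growth curve that
plateaus at 18 y, and weight is back-computed as BMI · height².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mortality import LifeTable
from .states import CLASS_ORDER, CutoffTable, WeightClass
from .survival import ParametricModel, TransitionSchedule, build_schedule

__all__ = [
    "GeneratorSpec",
    "simulate_longitudinal_cohort",
    "simulate_life_table",
    "calibrate_life_table",
    "simulate_cost_records",
    "default_true_models",
]

#: Initial weight-class distribution of the reference two-year-olds.
INITIAL_CLASS_P = {"NW": 0.8983, "OW": 0.0898, "OB1": 0.0086, "OB2": 0.0033}

#: Height (m) growth anchors: linear from age 2 to the adult value at 18.
HEIGHT_ANCHORS = {"female": (0.86, 1.67), "male": (0.87, 1.80)}


def default_true_models() -> dict:
    """The shipped default survival models as generator ground truth."""
    from .survival import load_default_models
    return load_default_models()


@dataclass
class GeneratorSpec:
    """Configuration of the longitudinal cohort generator.

    ``visit_ages`` fixes a deterministic visit schedule for everyone; when
    None, visits follow the survey-like default: annual checks at ages 2–8
    (children), then gaps drawn uniformly from ``adult_gap_range`` years.
    ``followup_range`` bounds each person's last possible visit age.
    """

    n_persons: int = 1000
    female_fraction: float = 0.48
    seed: int = 0
    true_models: dict | None = None          # (sex, aid, band) -> ParametricModel
    visit_ages: tuple | None = None
    child_visit_ages: tuple = (2, 3, 4, 5, 6, 8, 13)
    adult_gap_range: tuple = (4, 11)
    followup_range: tuple = (13, 75)
    dropout_per_visit: float = 0.15
    start_age: int = 2
    initial_class_p: dict = field(default_factory=lambda: dict(INITIAL_CLASS_P))


def _true_schedule(models: dict) -> TransitionSchedule:
    return build_schedule(models)


def _latent_path(rng, sex: str, schedule: TransitionSchedule, start_age: int,
                 end_age: int, p0: dict) -> list:
    """Annual latent weight classes from start_age to end_age inclusive.

    Moves are one class at a time; from OW both the progression and the
    regression hazard compete within the year.
    """
    classes = list(p0)
    probs = np.array([p0[c] for c in classes], dtype=float)
    cls = WeightClass(rng.choice(classes, p=probs / probs.sum()))
    path = [cls]
    up = {WeightClass.NW: 1, WeightClass.OW: 2, WeightClass.OB1: 3}
    down = {WeightClass.OW: 6, WeightClass.OB1: 5, WeightClass.OB2: 4}
    for age in range(start_age, end_age):
        p_up = schedule.probability(sex, up[cls], age) if cls in up else 0.0
        p_down = schedule.probability(sex, down[cls], age) if cls in down else 0.0
        u = rng.random()
        idx = CLASS_ORDER.index(cls)
        if u < p_up:
            cls = CLASS_ORDER[idx + 1]
        elif u < p_up + p_down:
            cls = CLASS_ORDER[idx - 1]
        path.append(cls)
    return path


def _height(sex: str, age: float) -> float:
    h2, h18 = HEIGHT_ANCHORS[sex]
    a = min(max(age, 2.0), 18.0)
    return h2 + (h18 - h2) * (a - 2.0) / 16.0


def _bmi_band(cls: WeightClass, age: float, sex: str, cutoffs: CutoffTable | None):
    if age <= 17 and cutoffs is not None:
        ow, ob1, ob2 = cutoffs.lookup(sex, age)
        lo_nw = max(ow - 3.5, 12.0)
    else:
        ow, ob1, ob2 = 25.0, 30.0, 35.0
        lo_nw = 18.0
    return {
        WeightClass.NW: (lo_nw, ow),
        WeightClass.OW: (ow, ob1),
        WeightClass.OB1: (ob1, ob2),
        WeightClass.OB2: (ob2, ob2 + 8.0),
    }[cls]


def simulate_longitudinal_cohort(
    spec: GeneratorSpec, cutoffs: CutoffTable | None = None
) -> pd.DataFrame:
    """Generate sparse longitudinal anthropometric records.

    Returns a frame ``person_id, sex, age, height, weight``.  Persons whose
    dropout leaves fewer than two visits are retained, so downstream
    preparation exercises its exclusion rule.
    """
    rng = np.random.default_rng(spec.seed)
    models = spec.true_models or default_true_models()
    schedule = _true_schedule(models)
    if cutoffs is None:
        from .datasets import load_child_cutoffs
        cutoffs = load_child_cutoffs()
    rows = []
    for pid in range(spec.n_persons):
        sex = "female" if rng.random() < spec.female_fraction else "male"
        if spec.visit_ages is not None:
            visits = [int(a) for a in spec.visit_ages]
        else:
            end = int(rng.integers(spec.followup_range[0], spec.followup_range[1] + 1))
            visits = [a for a in spec.child_visit_ages if a <= end]
            a = visits[-1] if visits else spec.start_age
            while True:
                a += int(rng.integers(spec.adult_gap_range[0], spec.adult_gap_range[1] + 1))
                if a > end:
                    break
                visits.append(a)
        if not visits:
            continue
        # non-informative dropout: truncate the visit list geometrically
        kept = [visits[0]]
        for v in visits[1:]:
            if rng.random() < spec.dropout_per_visit:
                break
            kept.append(v)
        last = kept[-1]
        path = _latent_path(rng, sex, schedule, spec.start_age,
                            max(last, spec.start_age), spec.initial_class_p)
        for v in kept:
            cls = path[v - spec.start_age]
            lo, hi = _bmi_band(cls, v, sex, cutoffs)
            bmi = rng.uniform(lo + 1e-6, hi - 1e-6)
            h = _height(sex, v)
            rows.append((f"p{pid}", sex, float(v), h, bmi * h * h))
    return pd.DataFrame(rows, columns=["person_id", "sex", "age", "height", "weight"])


def simulate_survival_records(
    n: int,
    model: ParametricModel,
    seed: int = 0,
    entry_max: float = 5.0,
    censor_horizon: float = 11.0,
) -> pd.DataFrame:
    """Direct left-truncated right-censored spells from one true model.

    Entry times are uniform on [0, entry_max] on the analysis clock; event
    times are drawn from the model conditional on exceeding entry
    (rejection-free via inverse CDF on the conditional survival); spells
    are censored at ``censor_horizon``.  Times are returned on the age
    clock with band entry at 0, i.e. columns entry/exit are analysis-clock
    and ``event`` is boolean.
    """
    rng = np.random.default_rng(seed)
    entry = rng.uniform(0.0, entry_max, size=n)
    u = rng.random(n)
    # inverse CDF of T | T > entry via bisection on S(t) = u * S(entry)
    s_entry = model.sf(entry)
    target = u * s_entry
    lo = entry.copy()
    hi = np.full(n, censor_horizon * 40.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        s_mid = model.sf(mid)
        go_right = s_mid > target
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
    t_event = 0.5 * (lo + hi)
    exit = np.minimum(t_event, censor_horizon)
    event = t_event < censor_horizon
    keep = exit > entry + 1e-9
    return pd.DataFrame({
        "person_id": [f"s{i}" for i in range(n)],
        "sex": "female",
        "analysis": 1,
        "entry": entry,
        "exit": exit,
        "event": event,
    })[keep]


def simulate_life_table(
    makeham_c: float = 0.0004,
    gompertz_lambda: float = 2.4e-5,
    gompertz_gamma: float = 0.098,
    sex_rate_ratio: float = 1.4,
) -> LifeTable:
    """Gompertz–Makeham life table m(age) = c + λ·e^{γ·age}, ages 0–100.

    ``sex_rate_ratio`` scales male rates relative to female.  The default
    parameters are calibrated (see :func:`calibrate_life_table`) so the
    engine's all-state life expectancy from age 2 is about 80 years.
    """
    if makeham_c < 0 or gompertz_lambda < 0:
        raise ValueError("rates must be non-negative")
    ages = np.arange(0, 101)
    base = makeham_c + gompertz_lambda * np.exp(gompertz_gamma * ages)
    rows = []
    for sex, scale in (("female", 1.0), ("male", sex_rate_ratio)):
        for a, m in zip(ages, base * scale):
            rows.append((sex, int(a), float(m)))
    return LifeTable(pd.DataFrame(rows, columns=["sex", "age", "rate"]))


def calibrate_life_table(
    target_le: float = 80.0,
    gompertz_gamma: float = 0.098,
    makeham_c: float = 0.0004,
    tol: float = 0.05,
) -> LifeTable:
    """Bisect the Gompertz rate λ so that life expectancy at 2 ≈ target.

    Life expectancy is evaluated the same way the engine does (annual
    cycles, end-of-cycle deaths, horizon truncation at 100), on the female
    arm.
    """
    def le_from(lam: float) -> float:
        lt = simulate_life_table(makeham_c, lam, gompertz_gamma)
        m = lt.rates("female")[:-1]  # ages 2..99
        surv = np.cumprod(np.exp(-m))
        return 2.0 + float(surv.sum())

    lo, hi = 1e-8, 1e-2
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if le_from(mid) > target_le:
            lo = mid
        else:
            hi = mid
        if abs(le_from(mid) - target_le) < tol:
            break
    lam = np.sqrt(lo * hi)
    return simulate_life_table(makeham_c, lam, gompertz_gamma)


def simulate_cost_records(
    n: int,
    seed: int = 0,
    participation: dict | None = None,
    mean_cost: dict | None = None,
    gamma_shape: float = 1.2,
    age_range: tuple = (20, 80),
    age_cost_slope: float = 0.01,
) -> pd.DataFrame:
    """Individual-level cost records from a known two-part process.

    ``participation`` maps weight class to P(cost > 0); ``mean_cost`` maps
    class to the conditional positive-cost mean at the age-range midpoint
    (EUR); costs scale exponentially in age with ``age_cost_slope`` per
    year.  Classes are assigned with realistic adult prevalences.
    """
    rng = np.random.default_rng(seed)
    participation = participation or {"NW": 0.55, "OW": 0.58, "OB1": 0.63, "OB2": 0.68}
    mean_cost = mean_cost or {"NW": 1400.0, "OW": 1550.0, "OB1": 2000.0, "OB2": 2200.0}
    classes = np.array(["NW", "OW", "OB1", "OB2"])
    class_p = np.array([0.40, 0.38, 0.15, 0.07])
    mid = 0.5 * (age_range[0] + age_range[1])
    rows = []
    for i in range(n):
        sex = "female" if rng.random() < 0.5 else "male"
        wc = rng.choice(classes, p=class_p)
        age = rng.uniform(*age_range)
        smoking = rng.choice(["never", "previous", "daily", "occasional"],
                             p=[0.45, 0.25, 0.22, 0.08])
        marital = rng.choice(["married", "never_married", "widowed", "divorced"],
                             p=[0.55, 0.25, 0.08, 0.12])
        cost = 0.0
        if rng.random() < participation[wc]:
            mean = mean_cost[wc] * np.exp(age_cost_slope * (age - mid))
            cost = rng.gamma(gamma_shape, mean / gamma_shape)
        rows.append((f"c{i}", sex, age, wc, smoking, marital, cost))
    return pd.DataFrame(rows, columns=[
        "person_id", "sex", "age", "weight_class", "smoking", "marital", "annual_cost",
    ])
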