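"""Incremental health-care costs of overweight and obesity.

Per-person annual costs are semicontinuous — many zeros, a skewed positive
tail — so they are modelled with a two-part model: a logistic regression for
P(cost > 0) and a gamma GLM with log link for E[cost | cost > 0], with
weight class, age, smoking status and marital status as covariates,
stratified by sex.  The model's expected cost is the product of the parts.
Incremental costs are average marginal effects vs the normal-weight class,
averaged over the estimation sample's covariate distribution with age set
to each year of age from 20 to 80; outside that range the schedule is
extended (flat above 80, configurable below 20).

Cost accumulation over a cohort trace multiplies state occupancy by the
per-state increment at each age, which makes the totals survival-adjusted
by construction; discounting divides by (1 + r)^(age - start_age).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .engine import CohortTrace
from .states import ConfigurationError, HealthState, STATE_CLASS
from .survival import EstimationError

__all__ = [
    "TwoPartCostModel",
    "TwoPartCostResults",
    "fit_two_part",
    "marginal_incremental_cost",
    "CostSchedule",
    "extend_cost_schedule",
    "expected_costs",
    "CostSummary",
]

SMOKING_LEVELS = ["never", "previous", "daily", "occasional"]
MARITAL_LEVELS = ["married", "never_married", "widowed", "divorced"]
CLASS_LEVELS = ["NW", "OW", "OB1", "OB2"]
COST_AGE_RANGE = (20, 80)


def _design(frame: pd.DataFrame) -> pd.DataFrame:
    """Shared covariate layout for both model parts (NW / never / married ref)."""
    X = pd.DataFrame(index=frame.index)
    X["const"] = 1.0
    for lvl in CLASS_LEVELS[1:]:
        X[f"class_{lvl}"] = (frame.weight_class == lvl).astype(float)
    X["age"] = frame.age.astype(float)
    for lvl in SMOKING_LEVELS[1:]:
        X[f"smoking_{lvl}"] = (frame.smoking == lvl).astype(float)
    for lvl in MARITAL_LEVELS[1:]:
        X[f"marital_{lvl}"] = (frame.marital == lvl).astype(float)
    return X


class TwoPartCostModel:
    """Two-part model for semicontinuous annual cost data (one sex).

    >>> res = TwoPartCostModel.from_dataframe(records, sex="female").fit()
    >>> res.predict_mean(records)        # P(>0) * E[cost | > 0]
    >>> res.incremental_cost("OB1", 45)  # AME vs NW at age 45, in EUR
    """

    def __init__(self, frame: pd.DataFrame, sex: str | None = None):
        required = {"weight_class", "age", "smoking", "marital", "annual_cost"}
        if not required.issubset(frame.columns):
            raise ConfigurationError(f"cost records need columns {sorted(required)}")
        if sex is not None and "sex" in frame.columns:
            frame = frame[frame.sex == sex]
        if (frame.annual_cost < 0).any():
            raise ConfigurationError("costs must be non-negative")
        self.sex = sex
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, sex: str | None = None):
        return cls(frame, sex)

    def fit(self) -> "TwoPartCostResults":
        y = self.frame.annual_cost.to_numpy(dtype=float)
        any_cost = (y > 0).astype(float)
        if any_cost.all() or not any_cost.any():
            raise EstimationError(
                "two-part model needs both zero and positive costs "
                f"(positives: {int(any_cost.sum())}/{len(y)})"
            )
        X = _design(self.frame)
        try:
            part1 = sm.Logit(any_cost, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # perfect separation and friends
            raise EstimationError(f"logistic part failed: {exc}") from exc
        if not part1.mle_retvals.get("converged", True):
            raise EstimationError(
                "logistic part did not converge (possible separation); "
                f"mle_retvals={part1.mle_retvals}"
            )
        pos = self.frame.annual_cost > 0
        Xp = X[pos]
        part2 = sm.GLM(
            y[pos], Xp, family=sm.families.Gamma(link=sm.families.links.Log())
        ).fit()
        return TwoPartCostResults(self, part1, part2)


class TwoPartCostResults:
    """Fitted two-part model; exposes predictions and marginal effects."""

    def __init__(self, model: TwoPartCostModel, part1, part2):
        self.model = model
        self.part1 = part1
        self.part2 = part2

    def predict_mean(self, frame: pd.DataFrame) -> np.ndarray:
        """Unconditional expected cost: P(cost>0) · E[cost | cost>0]."""
        X = _design(frame)
        return np.asarray(self.part1.predict(X)) * np.asarray(self.part2.predict(X))

    def incremental_cost(self, state, age: float) -> float:
        """Average marginal effect of a weight class vs NW at a given age.

        Counterfactual averaging over the estimation sample: every record's
        class is set to ``state`` (then NW) and its age to ``age``; the mean
        prediction difference is the increment in EUR.
        """
        return marginal_incremental_cost(self, self.model.sex, age, state)

    def summary(self) -> str:
        return (
            "Two-part cost model"
            + (f" ({self.model.sex})" if self.model.sex else "")
            + "\n--- Part 1: logit P(cost > 0) ---\n"
            + str(self.part1.summary())
            + "\n--- Part 2: gamma GLM (log link), positives ---\n"
            + str(self.part2.summary())
        )


def fit_two_part(records: pd.DataFrame, sex: str) -> TwoPartCostResults:
    """Fit the sex-stratified two-part cost model to individual records."""
    return TwoPartCostModel.from_dataframe(records, sex=sex).fit()


def marginal_incremental_cost(
    results: TwoPartCostResults, sex, age: float, state
) -> float:
    """AME of ``state`` vs NW at ``age`` over the sample covariate distribution."""
    lo, hi = COST_AGE_RANGE
    if not (lo <= age <= hi):
        raise ConfigurationError(
            f"age {age} outside the cost-estimation range {lo}..{hi}; "
            "use extend_cost_schedule for other ages"
        )
    state = str(getattr(state, "value", state))
    if state == "NW":
        return 0.0
    if state not in CLASS_LEVELS:
        raise ConfigurationError(f"unknown weight class {state!r}")
    base = results.model.frame.copy()
    base["age"] = float(age)
    cf = base.copy()
    cf["weight_class"] = state
    base["weight_class"] = "NW"
    return float(np.mean(results.predict_mean(cf) - results.predict_mean(base)))


@dataclass
class CostSchedule:
    """Incremental annual cost vs NW per (sex, state, age 2..100), EUR.

    The NW column is identically zero; ages 80+ repeat the age-80 value;
    ages below 20 follow the configured under-20 rule.
    """

    frame: pd.DataFrame  # columns sex, state, age, incremental_cost_eur

    def increment(self, sex: str, state, age: int) -> float:
        wc = STATE_CLASS[HealthState(state)] if isinstance(state, HealthState) else None
        label = wc.value if wc is not None else str(getattr(state, "value", state))
        if label == "NW":
            return 0.0
        sub = self.frame[
            (self.frame.sex == sex)
            & (self.frame.state == label)
            & (self.frame.age == int(age))
        ]
        if sub.empty:
            raise ConfigurationError(f"no cost row for {sex}/{label}/age {age}")
        return float(sub.incremental_cost_eur.iloc[0])

    def vector(self, sex: str, state_label: str, ages) -> np.ndarray:
        if state_label == "NW":
            return np.zeros(len(ages))
        sub = self.frame[(self.frame.sex == sex) & (self.frame.state == state_label)]
        merged = pd.DataFrame({"age": ages}).merge(sub, on="age", how="left")
        if merged.incremental_cost_eur.isna().any():
            missing = merged[merged.incremental_cost_eur.isna()].age.tolist()
            raise ConfigurationError(f"cost schedule missing {sex}/{state_label} ages {missing[:5]}")
        return merged.incremental_cost_eur.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CostSchedule":
        return cls(pd.read_csv(path))


def extend_cost_schedule(
    source, under20_rule: str = "zero", sexes=("female", "male")
) -> CostSchedule:
    """Build a full age-2..100 :class:`CostSchedule`.

    ``source`` is either a fitted :class:`TwoPartCostResults` per sex
    (dict), or a DataFrame of increments covering ages 20..80 with columns
    sex, state, age, incremental_cost_eur (a sex/state/ame_eur table without
    an age column is broadcast flat over 20..80).  Ages 81..100 repeat the
    age-80 value; ages 2..19 are zero (``under20_rule="zero"``) or repeat
    the age-20 value (``"constant_at_20"``).
    """
    if under20_rule not in ("zero", "constant_at_20"):
        raise ConfigurationError(f"unknown under-20 rule {under20_rule!r}")
    lo, hi = COST_AGE_RANGE
    core_ages = list(range(lo, hi + 1))
    rows = []
    for sex in sexes:
        for state in CLASS_LEVELS[1:]:
            if isinstance(source, dict):
                res = source[sex]
                core = [marginal_incremental_cost(res, sex, a, state) for a in core_ages]
            else:
                sub = source[(source.sex == sex) & (source.state == state)]
                if sub.empty:
                    raise ConfigurationError(f"no cost input for {sex}/{state}")
                if "age" in source.columns:
                    got = sub.sort_values("age")
                    if list(got.age) != core_ages:
                        raise ConfigurationError(
                            f"cost input for {sex}/{state} must cover ages {lo}..{hi}"
                        )
                    col = "incremental_cost_eur" if "incremental_cost_eur" in sub.columns else "ame_eur"
                    core = got[col].to_list()
                else:
                    col = "incremental_cost_eur" if "incremental_cost_eur" in sub.columns else "ame_eur"
                    core = [float(sub[col].iloc[0])] * len(core_ages)
            under = 0.0 if under20_rule == "zero" else core[0]
            for age in range(2, lo):
                rows.append((sex, state, age, under))
            for age, v in zip(core_ages, core):
                rows.append((sex, state, age, float(v)))
            for age in range(hi + 1, 101):
                rows.append((sex, state, age, core[-1]))
        for age in range(2, 101):
            rows.append((sex, "NW", age, 0.0))
    return CostSchedule(pd.DataFrame(
        rows, columns=["sex", "state", "age", "incremental_cost_eur"]
    ))


@dataclass
class CostSummary:
    """Survival-adjusted incremental cost streams for one cohort arm."""

    sex: str
    ages: np.ndarray
    annual: np.ndarray                 # whole-cohort, undiscounted
    annual_discounted: np.ndarray
    cohort_size: float
    discount_rate: float

    @property
    def annual_per_person(self) -> np.ndarray:
        return self.annual / self.cohort_size

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.annual)

    @property
    def cumulative_discounted(self) -> np.ndarray:
        return np.cumsum(self.annual_discounted)

    @property
    def total(self) -> float:
        return float(self.annual.sum())

    @property
    def total_discounted(self) -> float:
        return float(self.annual_discounted.sum())

    @property
    def total_per_person(self) -> float:
        return self.total / self.cohort_size

    @property
    def total_per_person_discounted(self) -> float:
        return self.total_discounted / self.cohort_size


def expected_costs(
    trace: CohortTrace,
    schedule: CostSchedule,
    discount_rate: float = 0.04,
    states=("OW", "OB1", "OB2"),
) -> CostSummary:
    """Accumulate survival-adjusted incremental costs over a cohort trace.

    annual(age) = Σ over states of occupancy(state, age) · increment(state,
    age); discounting divides by (1 + r)^(age - start_age); per-person
    numbers divide by the starting cohort size.
    """
    ages = trace.ages
    annual = np.zeros(len(ages), dtype=float)
    for label in states:
        if label == "NW":
            continue
        occ = trace.occupancy(HealthState(label))
        annual += occ * schedule.vector(trace.sex, label, ages)
    disc = annual / (1.0 + discount_rate) ** (ages - trace.start_age)
    return CostSummary(
        sex=trace.sex, ages=ages, annual=annual, annual_discounted=disc,
        cohort_size=trace.cohort_size, discount_rate=discount_rate,
    )
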