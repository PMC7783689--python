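"""BMI computation and weight-class classification.

Adults are classified with the WHO cutoffs (25 / 30 / 35 kg/m²); children
aged 2–17 with age- and sex-specific cutoff tables in the IOTF style.  All
class intervals are lower-inclusive, upper-exclusive, so a BMI exactly at a
threshold belongs to the heavier class ("35+" is grade-2 obesity).  The model
has no underweight state: adult BMI below 18 is classified normal weight.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "WeightClass",
    "HealthState",
    "CutoffTable",
    "compute_bmi",
    "classify_adult",
    "classify_child",
    "classify",
]

ADULT_CUTOFFS = (25.0, 30.0, 35.0)
CHILD_MAX_AGE = 17


class WeightClass(str, enum.Enum):
    """Observable weight class (the NW1/NW2 split lives in the Markov engine)."""

    NW = "NW"
    OW = "OW"
    OB1 = "OB1"
    OB2 = "OB2"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Severity order used for one-class-move bookkeeping.
CLASS_ORDER = [WeightClass.NW, WeightClass.OW, WeightClass.OB1, WeightClass.OB2]


class HealthState(str, enum.Enum):
    """Markov health state.  NW1 = always normal weight, NW2 = normal weight
    after having been overweight or obese; the two share all parameters."""

    NW1 = "NW1"
    NW2 = "NW2"
    OW = "OW"
    OB1 = "OB1"
    OB2 = "OB2"
    DEAD = "DEAD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed state order of every transition matrix / cohort trace.
STATE_ORDER = [
    HealthState.NW1,
    HealthState.NW2,
    HealthState.OW,
    HealthState.OB1,
    HealthState.OB2,
    HealthState.DEAD,
]

#: Weight class of each live health state.
STATE_CLASS = {
    HealthState.NW1: WeightClass.NW,
    HealthState.NW2: WeightClass.NW,
    HealthState.OW: WeightClass.OW,
    HealthState.OB1: WeightClass.OB1,
    HealthState.OB2: WeightClass.OB2,
}


class InvalidInputError(ValueError):
    """Raised on physically impossible anthropometric input."""


class ConfigurationError(KeyError):
    """Raised when a required table row / model cell is missing."""


def compute_bmi(height: float, weight: float) -> float:
    """Body mass index, weight / height² in kg/m².

    Parameters
    ----------
    height : float
        Standing height in metres (> 0).
    weight : float
        Body weight in kilograms (> 0).
    """
    if not (height > 0) or not (weight > 0):
        raise InvalidInputError(
            f"height and weight must be positive, got height={height}, weight={weight}"
        )
    return weight / height**2


def classify_adult(bmi: float) -> WeightClass:
    """Classify an adult BMI with the WHO cutoffs (lower-inclusive bands)."""
    if not bmi > 0:
        raise InvalidInputError(f"bmi must be positive, got {bmi}")
    ow, ob1, ob2 = ADULT_CUTOFFS
    if bmi >= ob2:
        return WeightClass.OB2
    if bmi >= ob1:
        return WeightClass.OB1
    if bmi >= ow:
        return WeightClass.OW
    return WeightClass.NW


@dataclass(frozen=True)
class CutoffTable:
    """Age/sex-specific child BMI cutoffs (kg/m²), ages 2–17.

    The table has one row per (sex, tabulated age) with the thresholds into
    overweight, grade-1 and grade-2 obesity.  Queries at non-tabulated ages
    use the row of the floored tabulated age.
    """

    frame: pd.DataFrame  # columns: sex, age, ow, ob1, ob2

    def __post_init__(self) -> None:
        f = self.frame
        required = {"sex", "age", "ow", "ob1", "ob2"}
        if not required.issubset(f.columns):
            raise ConfigurationError(f"cutoff table needs columns {sorted(required)}")
        bad = f[~((f.ow > 0) & (f.ow < f.ob1) & (f.ob1 < f.ob2))]
        if len(bad):
            raise ConfigurationError(
                f"cutoff thresholds must satisfy 0 < ow < ob1 < ob2; offending rows:\n{bad}"
            )

    @classmethod
    def from_csv(cls, path) -> "CutoffTable":
        return cls(pd.read_csv(path))

    def _index(self) -> dict:
        # cached (sex, tabulated age) -> thresholds; frozen dataclass, so the
        # cache lives in __dict__ via object.__setattr__
        cache = self.__dict__.get("_cache")
        if cache is None:
            cache = {}
            for row in self.frame.itertuples(index=False):
                cache.setdefault(row.sex, []).append(
                    (float(row.age), (float(row.ow), float(row.ob1), float(row.ob2)))
                )
            for sex in cache:
                cache[sex].sort()
            object.__setattr__(self, "_cache", cache)
        return cache

    def lookup(self, sex: str, age: float) -> tuple[float, float, float]:
        """Thresholds (ow, ob1, ob2) for the floored tabulated age."""
        rows = self._index().get(sex)
        if rows is None:
            raise ConfigurationError(f"no cutoff rows for sex={sex!r}")
        best = None
        for a, thr in rows:
            if a <= age:
                best = thr
            else:
                break
        if best is None:
            raise ConfigurationError(f"no cutoff row for sex={sex!r} at age {age}")
        return best


def classify_child(bmi: float, age: float, sex: str, cutoffs: CutoffTable) -> WeightClass:
    """Classify a child's BMI (ages 2–17) with age/sex-specific cutoffs.

    Bands are lower-inclusive like the adult rule; e.g. a 2-y-old girl with
    the reference cutoffs is overweight from 18.09 and grade-2 obese from
    21.13 kg/m² upwards.
    """
    if not bmi > 0:
        raise InvalidInputError(f"bmi must be positive, got {bmi}")
    ow, ob1, ob2 = cutoffs.lookup(sex, age)
    if bmi >= ob2:
        return WeightClass.OB2
    if bmi >= ob1:
        return WeightClass.OB1
    if bmi >= ow:
        return WeightClass.OW
    return WeightClass.NW


def classify(bmi: float, age: float, sex: str, cutoffs: CutoffTable | None = None) -> WeightClass:
    """Route to the child rule for ages ≤ 17, the adult rule otherwise."""
    if age <= CHILD_MAX_AGE:
        if cutoffs is None:
            raise ConfigurationError("child classification needs a cutoff table")
        return classify_child(bmi, age, sex, cutoffs)
    return classify_adult(bmi)
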