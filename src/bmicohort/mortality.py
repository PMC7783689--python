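"""Per-state annual death probabilities from a life table and hazard ratios.

Excess mortality of overweight and obesity enters on the rate scale: the
life-table mortality rate m(age, sex) is multiplied by the BMI-class hazard
ratio before conversion to an annual probability,

    q = 1 - exp(-m · HR),

which keeps q in [0, 1) for any finite rate and hazard ratio.  The NW1 and
NW2 states share the NW hazard ratio (of 1 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import ConfigurationError, HealthState, STATE_CLASS

__all__ = ["LifeTable", "HazardRatioTable", "death_probability"]


@dataclass(frozen=True)
class LifeTable:
    """Age- and sex-specific annual mortality rates.

    ``frame`` columns: sex, age, rate (per person-year, ≥ 0); must cover
    ages 2..100 for both sexes.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if not {"sex", "age", "rate"}.issubset(f.columns):
            raise ConfigurationError("life table needs columns sex, age, rate")
        if (f.rate < 0).any():
            raise ConfigurationError("life table rates must be non-negative")
        for sex in f.sex.unique():
            ages = set(f[f.sex == sex].age.astype(int))
            missing = set(range(2, 101)) - ages
            if missing:
                raise ConfigurationError(
                    f"life table missing ages {sorted(missing)[:5]}... for sex={sex}"
                )

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def _cache(self) -> dict:
        cache = self.__dict__.get("_rates")
        if cache is None:
            cache = {(r.sex, int(r.age)): float(r.rate)
                     for r in self.frame.itertuples(index=False)}
            object.__setattr__(self, "_rates", cache)
        return cache

    def rate(self, sex: str, age: int) -> float:
        m = self._cache().get((sex, int(age)))
        if m is None:
            raise ConfigurationError(f"no life-table row for sex={sex} age={age}")
        return m

    def rates(self, sex: str) -> np.ndarray:
        """Rates for ages 2..100 as a vector."""
        sub = self.frame[self.frame.sex == sex].sort_values("age")
        sub = sub[(sub.age >= 2) & (sub.age <= 100)]
        return sub.rate.to_numpy(dtype=float)


@dataclass(frozen=True)
class HazardRatioTable:
    """BMI-class × age-band hazard ratios vs normal weight.

    ``frame`` columns: state (NW/OW/OB1/OB2), age_lo, age_hi (band
    [age_lo, age_hi)), hr, optional hr_lo / hr_hi 95% CI bounds.  NW rows
    must be 1; bands must partition ages 2..100 without overlap.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if not {"state", "age_lo", "age_hi", "hr"}.issubset(f.columns):
            raise ConfigurationError("HR table needs columns state, age_lo, age_hi, hr")
        if (f.hr < 0).any():
            raise ConfigurationError("hazard ratios must be non-negative")
        nw = f[f.state == "NW"]
        if len(nw) and not np.allclose(nw.hr, 1.0):
            raise ConfigurationError("NW hazard ratios must equal 1")
        for state, sub in f.groupby("state"):
            covered = np.zeros(101, dtype=int)
            for _, row in sub.iterrows():
                covered[int(row.age_lo):int(row.age_hi)] += 1
            if np.any(covered[2:101] != 1):
                raise ConfigurationError(
                    f"HR bands for state {state} do not partition ages 2..100"
                )

    @classmethod
    def from_csv(cls, path) -> "HazardRatioTable":
        return cls(pd.read_csv(path))

    @classmethod
    def all_ones(cls) -> "HazardRatioTable":
        """Neutral table (HR = 1 everywhere) — useful for mortality-neutral checks."""
        rows = [(s, 0, 101, 1.0) for s in ("NW", "OW", "OB1", "OB2")]
        return cls(pd.DataFrame(rows, columns=["state", "age_lo", "age_hi", "hr"]))

    def _bands(self) -> dict:
        cache = self.__dict__.get("_band_cache")
        if cache is None:
            cache = {}
            for r in self.frame.itertuples(index=False):
                cache.setdefault(r.state, []).append(
                    (float(r.age_lo), float(r.age_hi), float(r.hr))
                )
            object.__setattr__(self, "_band_cache", cache)
        return cache

    def ratio(self, weight_class: str, age: float) -> float:
        for lo, hi, hr in self._bands().get(str(weight_class), ()):
            if lo <= age < hi:
                return hr
        raise ConfigurationError(f"no HR band for state={weight_class} age={age}")

    def ci(self, weight_class: str, age: float) -> tuple[float, float] | None:
        sub = self.frame[
            (self.frame.state == str(weight_class))
            & (self.frame.age_lo <= age)
            & (age < self.frame.age_hi)
        ]
        if sub.empty or "hr_lo" not in sub.columns or sub.hr_lo.isna().any():
            return None
        return float(sub.hr_lo.iloc[0]), float(sub.hr_hi.iloc[0])


def death_probability(
    lifetable: LifeTable, hrs: HazardRatioTable, sex: str, age: int, state: HealthState
) -> float:
    """Annual death probability q = 1 - exp(-m(age, sex) · HR(state, age))."""
    state = HealthState(state)
    if state is HealthState.DEAD:
        raise ConfigurationError("death probability undefined for the DEAD state")
    m = lifetable.rate(sex, age)
    hr = hrs.ratio(STATE_CLASS[state].value, age)
    return float(-np.expm1(-m * hr))
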