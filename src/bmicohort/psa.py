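"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by repeated model evaluation: survival
coefficient vectors are drawn as mean + L·z with L the lower Cholesky
factor of the block covariance (correlated multivariate-normal draws),
hazard ratios log-normally from their point estimate and 95% CI, and cost
increments from gamma distributions matched to mean and variance.  Each
iteration rebuilds the transition schedule and cost schedule, re-runs both
cohort arms and records the outcomes; 95% confidence bounds are the 2.5%
and 97.5% order statistics over iterations (the ⌈0.025·n⌉-th and
⌈0.975·n⌉-th sorted observations, no interpolation).

Randomness is organised as one stream per (iteration, block), with the
block stream keyed by a stable digest of the block name, so adding a block
leaves every other block's draws unchanged.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import CostSchedule, expected_costs
from .engine import ModelSpec, life_expectancy, prevalence_among_alive, run_cohort
from .mortality import HazardRatioTable, LifeTable
from .states import ConfigurationError
from .survival import ParametricModel, build_schedule

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalBlock",
    "HRBlock",
    "CostBlock",
    "ParameterUncertainty",
    "sample_parameters",
    "PSAResult",
    "run_psa",
    "percentile_bounds",
]


@dataclass(frozen=True)
class SurvivalBlock:
    """Uncertainty of one (sex, transition, band) coefficient vector."""

    family: str
    mean: tuple
    cov: tuple  # nested tuple rows; all-zero => degenerate


@dataclass(frozen=True)
class HRBlock:
    """Log-normal uncertainty of one (state, band) hazard ratio."""

    hr: float
    hr_lo: float | None = None
    hr_hi: float | None = None

    @property
    def sigma(self) -> float:
        if self.hr_lo is None or self.hr_hi is None or self.hr <= 0:
            return 0.0
        return max((math.log(self.hr_hi) - math.log(self.hr_lo)) / (2 * 1.959964), 0.0)


@dataclass(frozen=True)
class CostBlock:
    """Gamma uncertainty of one (sex, state) cost increment (mean, variance).

    Negative mean increments are drawn as a negated gamma around |mean|
    (sign-preserving), since the gamma is defined on positives.
    """

    mean: float
    var: float


@dataclass
class ParameterUncertainty:
    """All uncertain blocks of one PSA configuration."""

    survival: dict = field(default_factory=dict)  # (sex, aid, band) -> SurvivalBlock
    hr: dict = field(default_factory=dict)        # (state, age_lo) -> HRBlock
    cost: dict = field(default_factory=dict)      # (sex, state) -> CostBlock


def _block_rng(seed: int, iteration: int, name: str) -> np.random.Generator:
    digest = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, iteration, digest]))


def _draw_mvn(mean: np.ndarray, cov: np.ndarray, rng) -> np.ndarray:
    if not np.any(cov):
        return mean.copy()
    try:
        L = np.linalg.cholesky(cov + 1e-14 * np.eye(len(mean)))
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(f"covariance block is not PSD: {exc}") from exc
    return mean + L @ rng.standard_normal(len(mean))


def sample_parameters(u: ParameterUncertainty, seed: int, iteration: int = 0) -> dict:
    """One concrete parameter set, deterministic per (seed, iteration).

    Returns a dict with ``survival_models`` ((sex, aid, band) ->
    ParametricModel), ``hr_frame`` rows to overwrite hazard ratios, and
    ``cost_increments`` ((sex, state) -> EUR).
    """
    models = {}
    for key, blk in u.survival.items():
        rng = _block_rng(seed, iteration, f"survival:{key}")
        mean = np.asarray(blk.mean, dtype=float)
        cov = np.asarray(blk.cov, dtype=float)
        draw = _draw_mvn(mean, cov, rng)
        draw = _respect_positivity(blk.family, draw)
        models[key] = ParametricModel(blk.family, draw)
    hr_draws = {}
    for key, blk in u.hr.items():
        rng = _block_rng(seed, iteration, f"hr:{key}")
        s = blk.sigma
        if s == 0.0 or blk.hr <= 0:
            hr_draws[key] = blk.hr
        else:
            hr_draws[key] = float(np.exp(math.log(blk.hr) + s * rng.standard_normal()))
    cost_draws = {}
    for key, blk in u.cost.items():
        rng = _block_rng(seed, iteration, f"cost:{key}")
        if blk.var <= 0 or blk.mean == 0:
            cost_draws[key] = blk.mean
            continue
        m = abs(blk.mean)
        shape = m * m / blk.var
        scale = blk.var / m
        draw = float(rng.gamma(shape, scale))
        cost_draws[key] = draw if blk.mean > 0 else -draw
    return {"survival_models": models, "hr": hr_draws, "cost": cost_draws}


def _respect_positivity(family: str, params: np.ndarray) -> np.ndarray:
    """Clip scale/shape parameters to their positive domain after a draw."""
    p = params.copy()
    positive_idx = {
        "exponential": [0], "weibull": [1], "lognormal": [1],
        "loglogistic": [1], "gompertz": [1], "gengamma": [1],
    }[family]
    for i in positive_idx:
        p[i] = max(p[i], 1e-8)
    return p


def uncertainty_from_inputs(
    survival_models: dict,
    hrs: HazardRatioTable,
    cost_table: pd.DataFrame,
    rel_se: float = 0.05,
) -> ParameterUncertainty:
    """Build a PSA spec from point inputs with synthetic coefficient SEs.

    Survival blocks with no fitted covariance get independent normal SEs of
    ``rel_se`` × |coefficient| (floor 1e-3); HR blocks take their CI from
    the hazard-ratio table; cost blocks take mean/SE columns (``ame_eur``,
    ``se_eur``) from the cost table.
    """
    u = ParameterUncertainty()
    for key, model in survival_models.items():
        cov = model.cov
        if cov is None:
            se = np.maximum(np.abs(model.params) * rel_se, 1e-3)
            cov = np.diag(se**2)
        u.survival[key] = SurvivalBlock(model.family, tuple(model.params),
                                        tuple(map(tuple, np.asarray(cov))))
    for _, row in hrs.frame.iterrows():
        lo = float(row.hr_lo) if "hr_lo" in hrs.frame.columns and not pd.isna(row.hr_lo) else None
        hi = float(row.hr_hi) if "hr_hi" in hrs.frame.columns and not pd.isna(row.hr_hi) else None
        u.hr[(row.state, int(row.age_lo))] = HRBlock(float(row.hr), lo, hi)
    for _, row in cost_table.iterrows():
        u.cost[(row.sex, row.state)] = CostBlock(float(row.ame_eur), float(row.se_eur) ** 2)
    return u


@dataclass
class PSAResult:
    """Per-iteration outcomes and empirical percentile bounds."""

    outcomes: pd.DataFrame  # one row per completed iteration
    n_iter: int
    seed: int
    n_failed: int = 0

    def bounds(self, outcome: str) -> tuple[float, float]:
        return percentile_bounds(self.outcomes[outcome].to_numpy())

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in self.outcomes.columns:
            if col == "iteration":
                continue
            lo, hi = self.bounds(col)
            rows.append((col, self.outcomes[col].mean(), lo, hi))
        return pd.DataFrame(rows, columns=["outcome", "mean", "cb_lo", "cb_hi"])


def percentile_bounds(values: np.ndarray) -> tuple[float, float]:
    """2.5% / 97.5% order statistics (⌈0.025n⌉-th and ⌈0.975n⌉-th sorted)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    lo = max(math.ceil(0.025 * n), 1) - 1
    hi = max(math.ceil(0.975 * n), 1) - 1
    return float(v[lo]), float(v[hi])


def _apply_hr_draws(hrs: HazardRatioTable, draws: dict) -> HazardRatioTable:
    f = hrs.frame.copy()
    for (state, age_lo), hr in draws.items():
        mask = (f.state == state) & (f.age_lo == age_lo)
        f.loc[mask, "hr"] = hr
    f.loc[f.state == "NW", "hr"] = 1.0  # NW stays the reference
    return HazardRatioTable(f)


def _cost_schedule_from_draws(draws: dict, under20_rule: str = "zero") -> CostSchedule:
    from .economics import extend_cost_schedule
    rows = [(sex, state, v) for (sex, state), v in draws.items()]
    frame = pd.DataFrame(rows, columns=["sex", "state", "ame_eur"])
    return extend_cost_schedule(frame, under20_rule=under20_rule)


def run_psa(
    model_spec: ModelSpec,
    u: ParameterUncertainty,
    lifetable: LifeTable,
    hrs: HazardRatioTable,
    n_iter: int = 1000,
    seed: int = 17,
    prevalence_age: int = 75,
    max_failure_fraction: float = 0.05,
) -> PSAResult:
    """Run the full-model PSA.

    Each iteration rebuilds the transition schedule from the drawn survival
    coefficients, applies drawn hazard ratios and cost increments, runs
    both cohort arms, and records life expectancy, discounted and
    undiscounted cumulative per-person incremental costs, and obesity
    prevalence among the living at ``prevalence_age``.
    """
    rows = []
    n_failed = 0
    for it in range(n_iter):
        try:
            draw = sample_parameters(u, seed, it)
            schedule = build_schedule(draw["survival_models"])
            hrs_it = _apply_hr_draws(hrs, draw["hr"]) if draw["hr"] else hrs
            cost_sched = _cost_schedule_from_draws(draw["cost"]) if draw["cost"] else None
            row = {"iteration": it}
            for sex in ("female", "male"):
                trace = run_cohort(model_spec, schedule, lifetable, hrs_it, sex)
                tag = sex[0]
                row[f"le_{tag}"] = life_expectancy(trace, model_spec.half_cycle_correction)
                prev = prevalence_among_alive(trace, prevalence_age)
                row[f"prev_ob_{tag}"] = prev["OB1"] + prev["OB2"]
                if cost_sched is not None:
                    cs = expected_costs(trace, cost_sched, model_spec.discount_rate)
                    row[f"cost_pp_{tag}"] = cs.total_per_person
                    row[f"cost_pp_disc_{tag}"] = cs.total_per_person_discounted
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - failures are data, not bugs
            n_failed += 1
            logger.warning("PSA iteration %d failed: %s", it, exc)
            if n_failed > max_failure_fraction * n_iter:
                raise RuntimeError(
                    f"PSA aborted: {n_failed} failures out of {it + 1} iterations"
                ) from exc
    outcomes = pd.DataFrame(rows)
    return PSAResult(outcomes=outcomes, n_iter=n_iter, seed=seed, n_failed=n_failed)
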