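"""Restructuring sparse longitudinal anthropometry into survival records.

The pipeline is: linear interpolation of height and weight to annual
measurements (height plateaus at 18 y), classification of each person-age
into a weight class, then construction of left-truncated right-censored
spells for each of the six transition analyses (progression NW→OW, OW→OB1,
OB1→OB2; regression OB2→OB1, OB1→OW, OW→NW).  A spell opens at the first
age a person is observed in the origin class (delayed entry on the common
age clock) and closes at the first age in the destination class (event) or
at loss to follow-up / exit to a non-destination class (censoring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import CLASS_ORDER, CutoffTable, WeightClass
from .survival import TRANSITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "PrepReport",
    "interpolate_series",
    "annualize_states",
    "build_survival_records",
    "build_all_survival_records",
    "assign_bands",
]

RECORD_COLUMNS = ["person_id", "sex", "age", "height", "weight"]
SURVIVAL_COLUMNS = ["person_id", "sex", "analysis", "entry", "exit", "event"]

#: Band boundaries on the age clock; a spell crossing one is split there.
BAND_BOUNDS = [(2, 13, "child"), (13, 20, "adolescent"), (20, 200, "adult")]

#: Duration assigned to the pass-through spell when consecutive annual
#: classes jump two classes (no direct two-class arrow exists, so the jump is
#: decomposed into two one-class events at the same boundary).
PASS_THROUGH_DURATION = 0.5


@dataclass
class PrepReport:
    """Side counts from a preparation run."""

    n_excluded_single_obs: int = 0
    n_two_class_jumps: int = 0


def interpolate_series(
    records: pd.DataFrame,
    height_plateau_age: float = 18.0,
    report: PrepReport | None = None,
) -> pd.DataFrame:
    """Interpolate each person's measurements to one record per integer age.

    Weight is linear between adjacent measurements.  Height is linear while
    below ``height_plateau_age``; a measurement pair straddling the plateau
    age rises linearly to the later measured height at exactly the plateau
    age and is constant thereafter.  Persons with fewer than two records are
    excluded (their count is logged and recorded in ``report``).
    """
    records = pd.DataFrame(records, columns=records.columns)
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    out = []
    n_single = 0
    for (pid, sex), grp in records.groupby(["person_id", "sex"], sort=False):
        grp = grp.sort_values("age")
        if len(grp) < 2:
            n_single += 1
            continue
        ages = grp.age.to_numpy(dtype=float)
        hts = grp.height.to_numpy(dtype=float)
        wts = grp.weight.to_numpy(dtype=float)
        grid = np.arange(np.ceil(ages[0]), np.floor(ages[-1]) + 1)
        w_i = np.interp(grid, ages, wts)
        h_i = _interp_height(grid, ages, hts, height_plateau_age)
        for a, h, w in zip(grid, h_i, w_i):
            out.append((pid, sex, float(a), float(h), float(w)))
    if n_single:
        logger.info("interpolate_series: excluded %d person(s) with < 2 observations",
                    n_single)
    if report is not None:
        report.n_excluded_single_obs += n_single
    return pd.DataFrame(out, columns=RECORD_COLUMNS)


def _interp_height(grid, ages, hts, plateau):
    """Height interpolation with the growth-plateau rule."""
    # Build a piecewise-linear height curve on knot ages: measurement ages
    # below the plateau, the plateau age itself (valued at the first
    # measured height at or after the plateau, i.e. growth completes exactly
    # at the plateau), and constancy afterwards.
    ages = np.asarray(ages, dtype=float)
    hts = np.asarray(hts, dtype=float)
    if ages[-1] <= plateau:
        return np.interp(grid, ages, hts)
    if ages[0] >= plateau:
        # adult-only: height constant at each measurement; use the first
        return np.full_like(np.asarray(grid, dtype=float), hts[0])
    below = ages < plateau
    # adult height = first measurement at/after the plateau age
    adult_h = hts[~below][0]
    knots_a = np.concatenate([ages[below], [plateau]])
    knots_h = np.concatenate([hts[below], [adult_h]])
    out = np.interp(np.minimum(grid, plateau), knots_a, knots_h)
    return out


def annualize_states(
    annual_records: pd.DataFrame, cutoffs: CutoffTable
) -> pd.DataFrame:
    """Map annual records to weight classes (child rule for ages ≤ 17).

    Returns a frame ``person_id, sex, age, weight_class`` with consecutive
    integer ages per person.
    """
    rec = annual_records
    bmi = rec.weight.to_numpy(dtype=float) / rec.height.to_numpy(dtype=float) ** 2
    age = rec.age.to_numpy(dtype=float)
    sex = rec.sex.to_numpy()
    # vectorised thresholds: adult defaults, overwritten per (sex, child age)
    from .states import ADULT_CUTOFFS, CHILD_MAX_AGE
    thr = np.tile(np.asarray(ADULT_CUTOFFS), (len(rec), 1))
    child = age <= CHILD_MAX_AGE
    if child.any():
        key = pd.Series(list(zip(sex[child], np.floor(age[child]))))
        for (sx, a), idx in key.groupby(key).groups.items():
            try:
                thr[np.flatnonzero(child)[idx]] = cutoffs.lookup(sx, a)
            except Exception as exc:
                pids = rec.person_id.to_numpy()[np.flatnonzero(child)[idx]][:3]
                raise type(exc)(f"persons {list(pids)} age {a}: {exc}") from exc
    labels = np.array(["NW", "OW", "OB1", "OB2"])
    level = (bmi[:, None] >= thr).sum(axis=1)
    out = rec[["person_id", "sex", "age"]].copy()
    out["weight_class"] = labels[level]
    return out


def _expand_jumps(ages, classes, report: PrepReport | None):
    """Decompose two-class annual jumps into one-class steps.

    Returns (ages, classes) lists where a jump inserts the intermediate
    class at the boundary age; the pass-through is flagged by a fractional
    duplicate age (boundary age repeated), which the spell builder converts
    into a short spell of :data:`PASS_THROUGH_DURATION`.
    """
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    out_ages, out_cls = [ages[0]], [classes[0]]
    n_jumps = 0
    for a, c in zip(ages[1:], classes[1:]):
        prev = out_cls[-1]
        step = idx[c] - idx[prev]
        while abs(step) > 1:
            mid = CLASS_ORDER[idx[prev] + (1 if step > 0 else -1)]
            out_ages.append(a)
            out_cls.append(mid)
            n_jumps += 1
            prev = mid
            step = idx[c] - idx[prev]
        out_ages.append(a)
        out_cls.append(c)
    if n_jumps and report is not None:
        report.n_two_class_jumps += n_jumps
    if n_jumps:
        logger.info("decomposed %d two-class jump(s) into one-class steps", n_jumps)
    return out_ages, out_cls


def build_survival_records(
    series: pd.DataFrame, analysis_id: int, report: PrepReport | None = None
) -> pd.DataFrame:
    """Build spells for one analysis from an annual state series frame.

    ``series`` is the output of :func:`annualize_states`.  Each spell carries
    age-clock entry/exit times; re-entry into the origin class opens a new
    spell; exit to a non-destination class censors the spell at that age
    (cause-specific censoring).
    """
    if analysis_id not in TRANSITIONS:
        raise ValueError(f"analysis_id must be 1..6, got {analysis_id}")
    origin, dest = (WeightClass(x) for x in TRANSITIONS[analysis_id])
    rows = []
    for (pid, sex), grp in series.groupby(["person_id", "sex"], sort=False):
        grp = grp.sort_values("age")
        ages = grp.age.to_list()
        classes = [WeightClass(c) for c in grp.weight_class]
        ages, classes = _expand_jumps(ages, classes, report)
        open_entry = None
        for i, (a, c) in enumerate(zip(ages, classes)):
            if open_entry is None:
                if c == origin:
                    open_entry = a
                    # pass-through: same age appears twice, spell would be
                    # degenerate; stretch with the pass-through convention
                continue
            if c == origin:
                continue
            exit_age = a if a > open_entry else open_entry + PASS_THROUGH_DURATION
            rows.append((pid, sex, analysis_id, open_entry, exit_age, c == dest))
            open_entry = a if c == origin else None
        if open_entry is not None and ages[-1] > open_entry:
            rows.append((pid, sex, analysis_id, open_entry, ages[-1], False))
    out = pd.DataFrame(rows, columns=SURVIVAL_COLUMNS)
    if len(out):
        out["event"] = out["event"].astype(bool)
    return out


def build_all_survival_records(
    series: pd.DataFrame, report: PrepReport | None = None
) -> pd.DataFrame:
    """Spells for all six analyses, concatenated."""
    parts = [build_survival_records(series, aid, report) for aid in TRANSITIONS]
    return pd.concat(parts, ignore_index=True)


def assign_bands(records: pd.DataFrame) -> pd.DataFrame:
    """Assign each spell to an estimation band by its entry age.

    A spell crossing a band boundary (13 or 20) is split at the boundary;
    the later part enters the next band with delayed entry.  The returned
    frame adds a ``band`` column.
    """
    rows = []
    for rec in records.itertuples(index=False):
        entry, exit = float(rec.entry), float(rec.exit)
        for lo, hi, band in BAND_BOUNDS:
            if exit <= lo or entry >= hi:
                continue
            seg_entry = max(entry, lo)
            seg_exit = min(exit, hi)
            if seg_exit <= seg_entry:
                continue
            is_last = seg_exit == exit
            rows.append((rec.person_id, rec.sex, rec.analysis,
                         seg_entry, seg_exit, bool(rec.event) and is_last, band))
    return pd.DataFrame(rows, columns=SURVIVAL_COLUMNS + ["band"])
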