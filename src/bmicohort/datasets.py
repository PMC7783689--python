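"""Loaders for the small reference tables shipped with the package.

The shipped tables are configuration, not code: the child cutoff table is a
synthetic reference interpolating published age-2 anchors to the adult
cutoffs (substitute the full published IOTF table for real analyses); the
hazard-ratio table is a plausible synthetic fixture, not a meta-analysis
result; the default transition models carry the published Norwegian
survival estimates; the default cost increments carry the published average
marginal effects with synthetic standard errors.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .mortality import HazardRatioTable
from .states import CutoffTable

__all__ = [
    "load_child_cutoffs",
    "load_hazard_ratios",
    "load_default_cost_increments",
]


def _data(name: str):
    return files("bmicohort.data") / name


def load_child_cutoffs() -> CutoffTable:
    """Synthetic reference child BMI cutoffs, ages 2–17 both sexes."""
    return CutoffTable(pd.read_csv(_data("child_cutoffs_reference.csv")))


def load_hazard_ratios() -> HazardRatioTable:
    """Synthetic BMI-class × age-band mortality hazard ratios (NW = 1)."""
    return HazardRatioTable(pd.read_csv(_data("hazard_ratios_reference.csv")))


def load_default_cost_increments() -> pd.DataFrame:
    """Default incremental annual costs (EUR) with synthetic SEs."""
    return pd.read_csv(_data("default_cost_increments.csv"))
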