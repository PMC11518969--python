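"""Compile stratified rate tables into dense lookup arrays.

The engine indexes these arrays with integer codes each step instead of
merging DataFrames; compilation also verifies that every stratum the
simulation can reach is present (a missing stratum raises immediately rather
than producing silent NaN hazards mid-run).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codes
from .fixtures import RateTableSet

_SEX_INDEX = {name: i for i, name in enumerate(codes.SEXES)}
_RACE_INDEX = {name: i for i, name in enumerate(codes.RACE_ETHNICITIES)}
_NATIVITY_INDEX = {name: i for i, name in enumerate(codes.NATIVITIES)}
_AGE_INDEX = {lo: i for i, lo in enumerate(codes.AGE_GROUP_LOWER_BOUNDS)}
_MOVE_INDEX = {name: i for i, name in enumerate(codes.INTERNATIONAL_MOVE_TYPES)}


@dataclass
class RateLookups:
    mortality: np.ndarray  # (age, sex)
    fertility: np.ndarray  # (age,)
    domestic_individual: np.ndarray  # (age, sex, race)
    domestic_household: np.ndarray  # (age, sex, race) of the reference person
    emigration: np.ndarray  # (age, sex, race, nativity, state, move_type)
    states: list[str]
    state_index: dict[str, int]
    immigration_events_per_year: dict[str, float]


def _fill(table: pd.DataFrame, shape: tuple[int, ...], index_cols, name: str) -> np.ndarray:
    out = np.full(shape, np.nan)
    idx = tuple(
        np.array([mapper[v] for v in table[col]]) for col, mapper in index_cols
    )
    out[idx] = table["rate"].to_numpy(dtype=float)
    if np.isnan(out).any():
        raise KeyError(f"{name} rate table is missing strata")
    return out


def build_lookups(rates: RateTableSet) -> RateLookups:
    n_age = codes.N_AGE_GROUPS
    mortality = _fill(
        rates.mortality, (n_age, 2), [("age_lo", _AGE_INDEX), ("sex", _SEX_INDEX)], "mortality"
    )
    fert = np.full(n_age, np.nan)
    fert[[_AGE_INDEX[lo] for lo in rates.fertility["age_lo"]]] = rates.fertility["rate"].to_numpy()
    if np.isnan(fert).any():
        raise KeyError("fertility rate table is missing age groups")

    strata3 = [("age_lo", _AGE_INDEX), ("sex", _SEX_INDEX), ("race_ethnicity", _RACE_INDEX)]
    individual = _fill(rates.domestic_individual_migration, (n_age, 2, 7), strata3, "domestic individual")
    household = _fill(rates.domestic_household_migration, (n_age, 2, 7), strata3, "domestic household")

    states = sorted(rates.emigration["state"].unique())
    state_index = {s: i for i, s in enumerate(states)}
    emigration = _fill(
        rates.emigration,
        (n_age, 2, 7, 2, len(states), len(codes.INTERNATIONAL_MOVE_TYPES)),
        strata3 + [("nativity", _NATIVITY_INDEX), ("state", state_index), ("move_type", _MOVE_INDEX)],
        "emigration",
    )

    immigration = dict(
        zip(rates.immigration_counts["move_type"], rates.immigration_counts["events_per_year"].astype(float))
    )
    for mt in codes.INTERNATIONAL_MOVE_TYPES:
        immigration.setdefault(mt, 0.0)

    return RateLookups(
        mortality=mortality,
        fertility=fert,
        domestic_individual=individual,
        domestic_household=household,
        emigration=emigration,
        states=states,
        state_index=state_index,
        immigration_events_per_year=immigration,
    )
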