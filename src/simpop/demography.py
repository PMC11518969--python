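"""Mortality, fertility (with twinning and inheritance), and household
relationship maintenance.

Deaths follow the per-step probability implied by each simulant's (age group,
sex) all-cause hazard.  When a residential reference person dies (or moves
away), the oldest remaining present member becomes the new reference person
and the other members' relationships are remapped by a fixed kinship table.

Births follow an age-specific hazard applied to present female simulants; a
configurable fraction of birth events (default 4%) are twins.  Newborns
inherit household, race/ethnicity and (at name assignment) last name from the
single identified parent, are US-born with an SSN, and get a relationship to
the reference person derived from the parent's own relationship.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codes
from .engine_utils import rate_to_step_probability
from .state import PopulationState

# Parent's relationship to the reference person -> newborn's relationship.
# Minimal kinship-consistent mapping: a child of the reference person is a
# biological child; a child of the reference person's child is a grandchild;
# deeper or lateral kin collapse to "Other relative"; children of non-kin
# members are "Other nonrelative".  A GQ-resident parent keeps the newborn in
# the same GQ with no tracked relationship.
NEWBORN_RELATIONSHIP = {
    codes.REL_REFERENCE: codes.REL_BIO_CHILD,
    codes.REL_BIO_CHILD: codes.REL_GRANDCHILD,
    codes.REL_ADOPTED_CHILD: codes.REL_GRANDCHILD,
    codes.REL_STEPCHILD: codes.REL_GRANDCHILD,
    codes.REL_GRANDCHILD: codes.REL_OTHER_RELATIVE,
    codes.REL_SIBLING: codes.REL_OTHER_RELATIVE,
    codes.REL_PARENT: codes.REL_OTHER_RELATIVE,
    codes.REL_PARENT_IN_LAW: codes.REL_OTHER_RELATIVE,
    codes.REL_CHILD_IN_LAW: codes.REL_OTHER_RELATIVE,
    codes.REL_OTHER_RELATIVE: codes.REL_OTHER_RELATIVE,
    codes.REL_ROOMMATE: codes.REL_OTHER_NONRELATIVE,
    codes.REL_FOSTER_CHILD: codes.REL_OTHER_NONRELATIVE,
    codes.REL_OTHER_NONRELATIVE: codes.REL_OTHER_NONRELATIVE,
    codes.REL_NONE: codes.REL_NONE,
}


def newborn_relationship(parent_relationship: int) -> int:
    """Relationship of a newborn to the household reference person."""
    try:
        return NEWBORN_RELATIONSHIP[int(parent_relationship)]
    except KeyError:
        raise ValueError(f"unknown parent relationship code {parent_relationship}") from None


def _succession_relationship(member_rel: int, new_rp_old_rel: int) -> int:
    """Remap one member's relationship after reference-person succession.

    Business-rule table: members who shared a child-type relationship with
    the new reference person become siblings; other kin collapse to "Other
    relative"; non-kin members become "Other nonrelative"."""
    if member_rel in codes.CHILD_RELATIONSHIPS and new_rp_old_rel in codes.CHILD_RELATIONSHIPS:
        return codes.REL_SIBLING
    if member_rel == codes.REL_SIBLING and new_rp_old_rel == codes.REL_SIBLING:
        return codes.REL_SIBLING
    if member_rel in codes.KIN_RELATIONSHIPS:
        return codes.REL_OTHER_RELATIVE
    return codes.REL_OTHER_NONRELATIVE


def succeed_reference_person(state: PopulationState, household_id: int) -> None:
    """Promote the oldest remaining present member to reference person.

    If no present members remain the household is closed and its addresses
    vacated (never reused).  The oldest member is promoted even when
    unrealistically young (e.g. an unaccompanied minor).
    """
    if state.is_gq_household(household_id):
        return
    members = state.present_members(household_id)
    if len(members) == 0:
        state.close_household(household_id)
        return
    sims = state.simulants
    dobs = sims.loc[members, "date_of_birth"]
    new_rp = int(dobs.idxmin())  # earliest date of birth = oldest
    new_rp_old_rel = int(sims.at[new_rp, "relationship"])
    for member in members:
        member = int(member)
        if member == new_rp:
            continue
        old = int(sims.at[member, "relationship"])
        sims.at[member, "relationship"] = _succession_relationship(old, new_rp_old_rel)
    sims.at[new_rp, "relationship"] = codes.REL_REFERENCE
    state.households.at[household_id, "reference_person_id"] = new_rp


def resolve_departures(state: PopulationState, household_ids) -> None:
    """After members left the given households, restore reference-person
    invariants: run succession where the reference person departed, close
    households that emptied."""
    for hid in pd.unique(np.atleast_1d(np.asarray(household_ids, dtype=np.int64))):
        hid = int(hid)
        if state.is_gq_household(hid) or bool(state.households.at[hid, "closed"]):
            continue
        members = state.present_members(hid)
        if len(members) == 0:
            state.close_household(hid)
        elif int(state.households.at[hid, "reference_person_id"]) not in set(int(m) for m in members):
            succeed_reference_person(state, hid)


def apply_mortality(
    state: PopulationState,
    mortality_lookup: np.ndarray,
    date: dt.date,
    rng: np.random.Generator,
    *,
    step_days: int = 28,
) -> np.ndarray:
    """Kill present simulants at their (age group, sex) hazard; returns dead ids."""
    sims = state.simulants
    ids = state.at_risk_ids(date)
    if len(ids) == 0:
        return ids
    ages = state.ages_years(date, ids)
    rates = mortality_lookup[codes.age_group_index(ages), sims.loc[ids, "sex"].to_numpy()]
    if np.isnan(rates).any():
        raise KeyError("mortality rate missing for a populated stratum")
    p = rate_to_step_probability(rates, step_days)
    dead = ids[rng.random(len(ids)) < p]
    if len(dead) == 0:
        return dead
    sims.loc[dead, "status"] = codes.STATUS_DEAD
    sims.loc[dead, "status_date"] = pd.Timestamp(date)
    resolve_departures(state, sims.loc[dead, "household_id"].to_numpy())
    return dead


@dataclass
class BirthSummary:
    n_events: int
    n_twin_events: int
    newborn_ids: np.ndarray
    mother_ids: np.ndarray  # one entry per birth event


def apply_fertility(
    state: PopulationState,
    fertility_lookup: np.ndarray,
    date: dt.date,
    rng: np.random.Generator,
    *,
    twin_probability: float = 0.04,
    step_days: int = 28,
) -> BirthSummary:
    """Draw birth events among present female simulants and append newborns.

    Each event occurs at a uniformly random time within the step; twins share
    the event (same household, date of birth, and — once names are assigned —
    last name).
    """
    if not 0.0 <= twin_probability <= 1.0:
        raise ValueError("twin_probability must be a probability")
    sims = state.simulants
    ids = state.at_risk_ids(date)
    ids = ids[sims.loc[ids, "sex"].to_numpy() == codes.SEX_FEMALE]
    if len(ids) == 0:
        return BirthSummary(0, 0, np.array([], dtype=np.int64), np.array([], dtype=np.int64))
    ages = state.ages_years(date, ids)
    rates = fertility_lookup[codes.age_group_index(ages)]
    p = rate_to_step_probability(rates, step_days)
    mothers = ids[rng.random(len(ids)) < p]
    n_events = len(mothers)
    if n_events == 0:
        return BirthSummary(0, 0, np.array([], dtype=np.int64), mothers)

    twins = rng.random(n_events) < twin_probability
    offsets = rng.integers(0, step_days, n_events)
    counts = 1 + twins.astype(int)
    rep_mothers = np.repeat(mothers, counts)
    rep_offsets = np.repeat(offsets, counts)
    n_babies = int(counts.sum())

    baby_ids = state.new_simulant_ids(n_babies)
    mother_rows = sims.loc[rep_mothers]
    rel = mother_rows["relationship"].map(NEWBORN_RELATIONSHIP).astype(np.int8).to_numpy()
    dob = pd.Timestamp(date) + pd.to_timedelta(rep_offsets, unit="D")
    babies = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n_babies).astype(np.int8),
            "race_ethnicity": mother_rows["race_ethnicity"].to_numpy(),
            "nativity": np.full(n_babies, codes.NATIVITY_US, dtype=np.int8),
            "relationship": rel,
            "household_id": mother_rows["household_id"].to_numpy(),
            "has_ssn": np.ones(n_babies, dtype=bool),
            "employer_id": np.full(n_babies, codes.EMPLOYER_NONE, dtype=np.int64),
            "income_annual": np.zeros(n_babies),
            "status": np.full(n_babies, codes.STATUS_PRESENT, dtype=np.int8),
            "mother_id": rep_mothers.astype(np.int64),
            "date_of_birth": dob.to_numpy(),
            "status_date": np.full(n_babies, np.datetime64("NaT"), dtype="datetime64[ns]"),
        },
        index=pd.Index(baby_ids, name="simulant_id"),
    )
    state.simulants = pd.concat([sims, babies])
    return BirthSummary(n_events, int(twins.sum()), baby_ids, mothers)
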