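"""Domestic and international migration, and the address lifecycle.

Domestic *individual* moves pull one simulant out of their current living
situation into a new one-person household (as reference person), an existing
residential household (always as "Other nonrelative"), or group quarters of
a uniformly chosen kind; at most one individual move per simulant per step.
Domestic *household* moves relocate an entire multi-person household to a
fresh address without touching relationships.  Any mover of working age
changes employment.

Immigration adds entities cloned from the recent-immigrant subset of the
microdata (ages are not perturbed) via three move types: whole household,
GQ person, and non-reference person joining an existing household.
Emigration removes simulants permanently via the same three move types;
emigrated simulants never reappear in any observed dataset.  Vacated
addresses are never reused.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codes
from .engine_utils import rate_to_step_probability
from .population import _materialize
from .rates import RateLookups
from .state import PopulationState


def _open_residential_households(state: PopulationState) -> np.ndarray:
    """Ids of open residential households with at least one present member."""
    hh = state.households
    sims = state.simulants
    candidates = hh.index[(hh["kind"] == codes.KIND_RESIDENTIAL) & ~hh["closed"]]
    present_counts = sims.loc[state.present_mask(), "household_id"].value_counts()
    return candidates.intersection(present_counts.index).to_numpy()


@dataclass
class MoveSummary:
    individual_moves: int = 0
    household_moves: int = 0
    employment_changes: int = 0
    emigrants: int = 0
    emigration_events: dict[str, int] = field(default_factory=dict)
    immigrants: int = 0
    immigration_events: dict[str, int] = field(default_factory=dict)


def apply_domestic_individual(
    state: PopulationState,
    lookups: RateLookups,
    date: dt.date,
    rng: np.random.Generator,
    *,
    destination_split: tuple[float, float, float] = (0.5, 0.4, 0.1),
    step_days: int = 28,
    po_box_probability: float = 0.1,
    employment_hook=None,
) -> MoveSummary:
    """Hazard-driven individual moves; at most one per simulant per step."""
    split = np.asarray(destination_split, dtype=float)
    if split.shape != (3,) or not np.isclose(split.sum(), 1.0) or (split < 0).any():
        raise ValueError("destination_split must be a probability vector over 3 destinations")
    sims = state.simulants
    ids = state.at_risk_ids(date)
    summary = MoveSummary()
    if len(ids) == 0:
        return summary
    ages = state.ages_years(date, ids)
    rates = lookups.domestic_individual[
        codes.age_group_index(ages),
        sims.loc[ids, "sex"].to_numpy(),
        sims.loc[ids, "race_ethnicity"].to_numpy(),
    ]
    movers = ids[rng.random(len(ids)) < rate_to_step_probability(rates, step_days)]
    if len(movers) == 0:
        return summary

    old_households = sims.loc[movers, "household_id"].to_numpy()
    destinations = rng.choice(3, size=len(movers), p=split)
    candidates = _open_residential_households(state)

    new_hh_rows = {}
    for mover, old_hid, dest in zip(movers, old_households, destinations):
        mover = int(mover)
        if dest == 1 and len(candidates) > 0:
            # Join an existing residential household, uniformly chosen.
            target = int(rng.choice(candidates))
            for _ in range(10):
                if target != old_hid:
                    break
                target = int(rng.choice(candidates))
            if target == old_hid:
                dest = 0  # only own household available: establish a new one
            else:
                sims.at[mover, "household_id"] = target
                sims.at[mover, "relationship"] = codes.REL_OTHER_NONRELATIVE
        elif dest == 1:
            dest = 0
        if dest == 0:
            hid = int(state.new_household_ids(1)[0])
            phys = state.addresses.new_address(rng)
            mail = (
                state.addresses.new_address(rng, po_box=True)
                if rng.random() < po_box_probability
                else phys
            )
            new_hh_rows[hid] = (codes.KIND_RESIDENTIAL, phys, mail, mover, False)
            sims.at[mover, "household_id"] = hid
            sims.at[mover, "relationship"] = codes.REL_REFERENCE
        elif dest == 2:
            kind = int(rng.choice(codes.GQ_KIND_CODES))
            sims.at[mover, "household_id"] = state.gq_units[kind]
            sims.at[mover, "relationship"] = codes.REL_NONE

    if new_hh_rows:
        frame = pd.DataFrame.from_dict(
            new_hh_rows,
            orient="index",
            columns=["kind", "physical_address_id", "mailing_address_id", "reference_person_id", "closed"],
        )
        frame.index.name = "household_id"
        state.households = pd.concat([state.households, frame.astype(state.households.dtypes.to_dict())])

    from .demography import resolve_departures

    resolve_departures(state, old_households)

    summary.individual_moves = len(movers)
    if employment_hook is not None:
        working = movers[
            (state.ages_years(date, movers) >= codes.WORKING_AGE)
            & (sims.loc[movers, "employer_id"].to_numpy() != codes.EMPLOYER_NONE)
        ]
        if len(working):
            employment_hook(working)
        summary.employment_changes = len(working)
    return summary


def apply_domestic_household(
    state: PopulationState,
    lookups: RateLookups,
    date: dt.date,
    rng: np.random.Generator,
    *,
    step_days: int = 28,
    po_box_probability: float = 0.1,
    employment_hook=None,
) -> MoveSummary:
    """Whole-household moves: fresh address, relationships untouched.

    Only residential households with more than one present member are
    eligible; the hazard is read off the reference person's demographics.
    """
    sims = state.simulants
    hh = state.households
    summary = MoveSummary()
    present_counts = sims.loc[state.present_mask(), "household_id"].value_counts()
    eligible = hh.index[
        (hh["kind"] == codes.KIND_RESIDENTIAL)
        & ~hh["closed"]
        & (present_counts.reindex(hh.index, fill_value=0) > 1)
    ]
    if len(eligible) == 0:
        return summary
    rp = hh.loc[eligible, "reference_person_id"].to_numpy()
    keep = rp >= 0
    eligible, rp = eligible[keep], rp[keep]
    if len(eligible) == 0:
        return summary
    rp_rows = sims.loc[rp]
    ages = state.ages_years(date, rp)
    rates = lookups.domestic_household[
        codes.age_group_index(ages), rp_rows["sex"].to_numpy(), rp_rows["race_ethnicity"].to_numpy()
    ]
    moving = eligible.to_numpy()[rng.random(len(eligible)) < rate_to_step_probability(rates, step_days)]
    if len(moving) == 0:
        return summary

    all_movers = []
    for hid in moving:
        hid = int(hid)
        old_phys = int(hh.at[hid, "physical_address_id"])
        old_mail = int(hh.at[hid, "mailing_address_id"])
        phys = state.addresses.new_address(rng)
        mail = (
            state.addresses.new_address(rng, po_box=True)
            if rng.random() < po_box_probability
            else phys
        )
        hh.at[hid, "physical_address_id"] = phys
        hh.at[hid, "mailing_address_id"] = mail
        state.addresses.vacate([old_phys, old_mail])
        all_movers.append(state.present_members(hid).to_numpy())

    summary.household_moves = len(moving)
    if employment_hook is not None and all_movers:
        movers = np.concatenate(all_movers)
        working = movers[
            (state.ages_years(date, movers) >= codes.WORKING_AGE)
            & (sims.loc[movers, "employer_id"].to_numpy() != codes.EMPLOYER_NONE)
        ]
        if len(working):
            employment_hook(working)
        summary.employment_changes = len(working)
    return summary


def apply_emigration(
    state: PopulationState,
    lookups: RateLookups,
    date: dt.date,
    rng: np.random.Generator,
    *,
    step_days: int = 28,
) -> MoveSummary:
    """International out-migration by household, GQ-person and non-reference moves.

    Emigrants get status "emigrated" permanently; household moves remove the
    whole unit (and close it), and non-reference moves can never remove a
    reference person, so they never trigger succession.
    """
    sims = state.simulants
    hh = state.households
    summary = MoveSummary(emigration_events={mt: 0 for mt in codes.INTERNATIONAL_MOVE_TYPES})
    ids = state.at_risk_ids(date)
    if len(ids) == 0:
        return summary

    hh_of = sims.loc[ids, "household_id"].to_numpy()
    kinds = hh.loc[hh_of, "kind"].to_numpy()
    phys = hh.loc[hh_of, "physical_address_id"].to_numpy()
    states_of = state.addresses.state_of(phys)
    state_idx = np.array([lookups.state_index.get(s, 0) for s in states_of])
    ages = state.ages_years(date, ids)
    base_idx = (
        codes.age_group_index(ages),
        sims.loc[ids, "sex"].to_numpy(),
        sims.loc[ids, "race_ethnicity"].to_numpy(),
        sims.loc[ids, "nativity"].to_numpy(),
        state_idx,
    )
    is_gq = kinds != codes.KIND_RESIDENTIAL
    rel = sims.loc[ids, "relationship"].to_numpy()
    is_rp = rel == codes.REL_REFERENCE

    emigrated: list[np.ndarray] = []

    # Household-type moves, triggered through the reference person's hazard.
    mt = codes.INTERNATIONAL_MOVE_TYPES.index(codes.MOVE_HOUSEHOLD)
    rates = lookups.emigration[(*base_idx, np.full(len(ids), mt))]
    draws = rng.random(len(ids))
    trigger_rp = ids[(draws < rate_to_step_probability(rates, step_days)) & is_rp & ~is_gq]
    for rp_id in trigger_rp:
        hid = int(sims.at[int(rp_id), "household_id"])
        members = state.present_members(hid).to_numpy()
        emigrated.append(members)
        summary.emigration_events[codes.MOVE_HOUSEHOLD] += 1
        state.close_household(hid)

    gone = set(np.concatenate(emigrated).tolist()) if emigrated else set()

    mt = codes.INTERNATIONAL_MOVE_TYPES.index(codes.MOVE_GQ_PERSON)
    rates = lookups.emigration[(*base_idx, np.full(len(ids), mt))]
    draws = rng.random(len(ids))
    gq_movers = ids[(draws < rate_to_step_probability(rates, step_days)) & is_gq]
    gq_movers = np.array([i for i in gq_movers if i not in gone], dtype=np.int64)
    if len(gq_movers):
        emigrated.append(gq_movers)
        summary.emigration_events[codes.MOVE_GQ_PERSON] = len(gq_movers)
        gone.update(gq_movers.tolist())

    mt = codes.INTERNATIONAL_MOVE_TYPES.index(codes.MOVE_NON_REFERENCE)
    rates = lookups.emigration[(*base_idx, np.full(len(ids), mt))]
    draws = rng.random(len(ids))
    nonref = ids[(draws < rate_to_step_probability(rates, step_days)) & ~is_gq & ~is_rp]
    nonref = np.array([i for i in nonref if i not in gone], dtype=np.int64)
    if len(nonref):
        emigrated.append(nonref)
        summary.emigration_events[codes.MOVE_NON_REFERENCE] = len(nonref)

    if emigrated:
        all_gone = np.unique(np.concatenate(emigrated))
        sims.loc[all_gone, "status"] = codes.STATUS_EMIGRATED
        sims.loc[all_gone, "status_date"] = pd.Timestamp(date)
        summary.emigrants = len(all_gone)
    return summary


class ImmigrationSource:
    """Samples immigrating entities from the recent-immigrant microdata subset."""

    def __init__(self, microdata: pd.DataFrame):
        recent = microdata["recent_immigrant_flag"].astype(bool)
        gq = microdata["gq_flag"].astype(bool)
        self.microdata = microdata
        # Households containing at least one recent immigrant, sampled whole.
        recent_hh_keys = microdata.loc[recent & ~gq, "household_key"].unique()
        groups = microdata.loc[~gq].groupby("household_key").indices
        self.household_groups = [
            microdata.loc[~gq].index.to_numpy()[groups[k]] for k in recent_hh_keys if k in groups
        ]
        hh_w = []
        for rows in self.household_groups:
            sub = microdata.loc[rows]
            ref = sub.loc[sub["relationship_code"] == "Reference person", "weight"]
            hh_w.append(float(ref.iloc[0]) if len(ref) else float(sub["weight"].mean()))
        self.household_weights = np.asarray(hh_w, dtype=float)
        self.person_index = microdata.index[recent].to_numpy()
        self.person_weights = microdata.loc[recent, "weight"].to_numpy(dtype=float)

    def sample_households(self, n: int, rng: np.random.Generator) -> list[np.ndarray]:
        if n and not self.household_groups:
            raise RuntimeError("no recent-immigrant households available in microdata")
        if n == 0:
            return []
        p = self.household_weights / self.household_weights.sum()
        picks = rng.choice(len(self.household_groups), size=n, p=p)
        return [self.household_groups[i] for i in picks]

    def sample_persons(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n and not len(self.person_index):
            raise RuntimeError("no recent-immigrant persons available in microdata")
        if n == 0:
            return np.array([], dtype=np.int64)
        p = self.person_weights / self.person_weights.sum()
        return rng.choice(self.person_index, size=n, p=p)


def apply_immigration(
    state: PopulationState,
    source: ImmigrationSource,
    lookups: RateLookups,
    date: dt.date,
    rng: np.random.Generator,
    *,
    scale: float = 1.0,
    step_days: int = 28,
    ssn_foreign_born_probability: float = 0.5,
    po_box_probability: float = 0.1,
) -> MoveSummary:
    """Poisson-drawn immigration events; entity ages are not perturbed.

    Yearly event counts (per reference population, scaled by ``scale``) are
    converted to per-step Poisson means; rates are constant over time.
    """
    summary = MoveSummary(immigration_events={mt: 0 for mt in codes.INTERNATIONAL_MOVE_TYPES})
    step_fraction = step_days / codes.DAYS_PER_YEAR
    means = {
        mt: lookups.immigration_events_per_year.get(mt, 0.0) * scale * step_fraction
        for mt in codes.INTERNATIONAL_MOVE_TYPES
    }
    counts = {mt: int(rng.poisson(m)) if m > 0 else 0 for mt, m in means.items()}
    sims_frames = []

    for rows_idx in source.sample_households(counts[codes.MOVE_HOUSEHOLD], rng):
        rows = source.microdata.loc[rows_idx]
        hid = int(state.new_household_ids(1)[0])
        phys = state.addresses.new_address(rng)
        mail = (
            state.addresses.new_address(rng, po_box=True) if rng.random() < po_box_probability else phys
        )
        rel = rows["relationship_code"].map(codes.RELATIONSHIP_TO_CODE).astype(np.int8).to_numpy()
        frame = _materialize(
            rows, rel, hid, 0.0, date, rng, state, ssn_foreign_born_probability, perturb=False
        )
        ref_sim = int(frame.index[rel == codes.REL_REFERENCE][0])
        new_row = pd.DataFrame.from_dict(
            {hid: (codes.KIND_RESIDENTIAL, phys, mail, ref_sim, False)},
            orient="index",
            columns=["kind", "physical_address_id", "mailing_address_id", "reference_person_id", "closed"],
        )
        new_row.index.name = "household_id"
        state.households = pd.concat([state.households, new_row.astype(state.households.dtypes.to_dict())])
        sims_frames.append(frame)
        summary.immigration_events[codes.MOVE_HOUSEHOLD] += 1

    for person_idx in source.sample_persons(counts[codes.MOVE_GQ_PERSON], rng):
        row = source.microdata.loc[[person_idx]]
        if bool(row["gq_flag"].iloc[0]):
            institutional = bool(row["institutional_flag"].iloc[0])
        else:
            institutional = bool(rng.random() < 0.5)
        kind = (
            int(rng.choice(codes.INSTITUTIONAL_GQ_CODES))
            if institutional
            else int(rng.choice(codes.NONINSTITUTIONAL_GQ_CODES))
        )
        frame = _materialize(
            row,
            np.array([codes.REL_NONE], dtype=np.int8),
            state.gq_units[kind],
            0.0,
            date,
            rng,
            state,
            ssn_foreign_born_probability,
            perturb=False,
        )
        sims_frames.append(frame)
        summary.immigration_events[codes.MOVE_GQ_PERSON] += 1

    n_nonref = counts[codes.MOVE_NON_REFERENCE]
    if n_nonref:
        candidates = _open_residential_households(state)
        if len(candidates) == 0:
            raise RuntimeError("no open residential household to receive immigrants")
        for person_idx in source.sample_persons(n_nonref, rng):
            row = source.microdata.loc[[person_idx]]
            rel_code = codes.RELATIONSHIP_TO_CODE.get(row["relationship_code"].iloc[0], codes.REL_NONE)
            if rel_code in (codes.REL_REFERENCE, codes.REL_NONE):
                rel_code = codes.REL_OTHER_NONRELATIVE
            target = int(rng.choice(candidates))
            frame = _materialize(
                row,
                np.array([rel_code], dtype=np.int8),
                target,
                0.0,
                date,
                rng,
                state,
                ssn_foreign_born_probability,
                perturb=False,
            )
            sims_frames.append(frame)
            summary.immigration_events[codes.MOVE_NON_REFERENCE] += 1

    if sims_frames:
        new_sims = pd.concat(sims_frames)
        state.simulants = pd.concat([state.simulants, new_sims])
        summary.immigrants = len(new_sims)
    return summary
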