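"""Starting-population construction.

Entities — whole residential households or individual group-quarters
residents — are sampled from microdata with probability proportional to their
sampling weight, with replacement, until the target simulant count is
reached.  Because a source microdata table is typically a small sample of the
population it represents, many simulants descend from the same source record;
to avoid unrealistically identical clones each sampled entity receives a
shared age perturbation: integer ages are first made precise by adding a
uniform fraction of a year, then shifted by one standard-normal draw per
entity, and any resulting negative age has its sign flipped.
"""
from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from . import codes
from .fixtures import AddressLexicon
from .state import AddressRegistry, PopulationState, empty_households, empty_simulants


def map_race_ethnicity(race_code: str, hispanic_flag: bool) -> str:
    """Composite a raw race code and Hispanic-ethnicity flag into one of the
    seven exhaustive, mutually exclusive race/ethnicity categories.

    Hispanic ethnicity takes precedence: any record flagged Hispanic maps to
    "Latino" regardless of reported race.
    """
    if race_code not in codes.MICRODATA_RACE_CODES:
        raise ValueError(f"unknown race code: {race_code!r}")
    if hispanic_flag:
        return "Latino"
    return codes._RACE_CODE_TO_COMPOSITE[race_code]


def map_race_ethnicity_codes(race_codes: np.ndarray, hispanic: np.ndarray) -> np.ndarray:
    """Vectorized composite mapping returning integer category codes."""
    unknown = set(np.unique(race_codes)) - set(codes.MICRODATA_RACE_CODES)
    if unknown:
        raise ValueError(f"unknown race codes: {unknown}")
    lookup = {
        rc: codes.RACE_ETHNICITIES.index(codes._RACE_CODE_TO_COMPOSITE[rc])
        for rc in codes.MICRODATA_RACE_CODES
    }
    out = np.array([lookup[rc] for rc in race_codes], dtype=np.int8)
    out[np.asarray(hispanic, dtype=bool)] = codes.RACE_LATINO
    return out


def perturb_ages(precise_ages, shift: float) -> np.ndarray:
    """Apply one shared normal age shift to all members of a sampled entity.

    Each output equals input + shift; any negative result has its sign
    flipped (so a shift that pushes only an infant negative reflects just
    that member back to a small positive age).
    """
    out = np.asarray(precise_ages, dtype=float) + shift
    return np.where(out < 0, -out, out)


def assign_gq_type(institutional_flag: bool, rng: np.random.Generator) -> int:
    """Uniformly choose a GQ kind consistent with institutional status."""
    pool = codes.INSTITUTIONAL_GQ_CODES if institutional_flag else codes.NONINSTITUTIONAL_GQ_CODES
    return int(rng.choice(pool))


def derive_dob(precise_age: float, reference_date: dt.date) -> dt.date:
    """Date of birth consistent with a precise age at a reference date."""
    if precise_age < 0:
        raise ValueError("precise_age must be non-negative")
    return reference_date - dt.timedelta(days=round(precise_age * codes.DAYS_PER_YEAR))


def _derive_dob_vector(precise_ages: np.ndarray, reference_date: dt.date) -> np.ndarray:
    days = np.round(np.asarray(precise_ages, dtype=float) * codes.DAYS_PER_YEAR).astype("timedelta64[D]")
    return np.datetime64(reference_date, "D") - days


def initialize_population(
    microdata: pd.DataFrame,
    target_size: int,
    start_date: dt.date,
    lexicon: AddressLexicon,
    seed: int | np.random.Generator = 0,
    *,
    po_box_probability: float = 0.1,
    ssn_foreign_born_probability: float = 0.5,
) -> PopulationState:
    """Build the starting population by weighted entity sampling from microdata.

    Entities (whole non-GQ households, or individual GQ persons) are drawn
    with replacement, probability proportional to weight, until the present
    simulant count reaches ``target_size``; household internal structure is
    preserved and each entity gets one shared age shift.
    """
    if len(microdata) == 0:
        raise ValueError("cannot initialize from empty microdata")
    if target_size < 1:
        raise ValueError("target_size must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    gq_mask = microdata["gq_flag"].astype(bool).to_numpy()
    hh_rows = microdata.loc[~gq_mask]
    gq_rows = microdata.loc[gq_mask]

    # Entity catalogue: households first, then GQ persons.
    hh_groups: list[np.ndarray] = []
    hh_weights: list[float] = []
    if len(hh_rows):
        ref = hh_rows["relationship_code"] == "Reference person"
        for key, idx in hh_rows.groupby("household_key").indices.items():
            rows = hh_rows.iloc[idx]
            w = rows.loc[ref.iloc[idx].to_numpy(), "weight"]
            hh_groups.append(hh_rows.index.to_numpy()[idx])
            hh_weights.append(float(w.iloc[0]) if len(w) else float(rows["weight"].mean()))
    entity_weights = np.array(hh_weights + gq_rows["weight"].tolist(), dtype=float)
    if not len(entity_weights):
        raise ValueError("microdata contains no sampleable entities")
    probs = entity_weights / entity_weights.sum()
    n_households_entities = len(hh_groups)
    gq_index = gq_rows.index.to_numpy()

    state = PopulationState(
        simulants=empty_simulants(),
        households=empty_households(),
        addresses=AddressRegistry(lexicon),
    )

    # One unit per GQ kind, shared by all its residents.
    gq_unit_rows = {}
    for kind in codes.GQ_KIND_CODES:
        hid = int(state.new_household_ids(1)[0])
        addr = state.addresses.new_address(rng)
        gq_unit_rows[hid] = (kind, addr, addr, -1, False)
        state.gq_units[kind] = hid

    # Draw entities (with replacement, weight-proportional) until the batch
    # covers the target present-person count.
    entity_sizes = np.array([len(g) for g in hh_groups] + [1] * len(gq_index), dtype=np.int64)
    mean_entity_size = float(entity_sizes.mean())
    drawn: list[np.ndarray] = []
    total = 0
    while total < target_size:
        batch = max(int(np.ceil((target_size - total) / mean_entity_size)), 16)
        chunk = rng.choice(len(entity_weights), size=batch, p=probs)
        csum = total + np.cumsum(entity_sizes[chunk])
        cut = int(np.searchsorted(csum, target_size)) + 1
        drawn.append(chunk[:cut])
        total = int(csum[min(cut, len(csum)) - 1])
    entities = np.concatenate(drawn)
    shifts = rng.standard_normal(len(entities))

    hh_rows_out: dict[int, tuple] = dict(gq_unit_rows)
    sim_frames: list[pd.DataFrame] = []

    # Residential-household entities, materialized in one vectorized pass.
    is_hh = entities < n_households_entities
    hh_entities = entities[is_hh]
    if len(hh_entities):
        sizes = entity_sizes[hh_entities]
        row_labels = np.concatenate([hh_groups[e] for e in hh_entities])
        rows = microdata.loc[row_labels]
        hids = state.new_household_ids(len(hh_entities))
        per_person_hid = np.repeat(hids, sizes)
        per_person_shift = np.repeat(shifts[is_hh], sizes)
        rel = rows["relationship_code"].map(codes.RELATIONSHIP_TO_CODE).astype(np.int8).to_numpy()
        frame = _materialize_vector(
            rows, rel, per_person_hid, per_person_shift, start_date, rng, state,
            ssn_foreign_born_probability,
        )
        sim_frames.append(frame)
        ref_sims = frame.index.to_numpy()[rel == codes.REL_REFERENCE]
        po_box = rng.random(len(hh_entities)) < po_box_probability
        for hid, ref_sim, pob in zip(hids, ref_sims, po_box):
            phys = state.addresses.new_address(rng)
            mail = state.addresses.new_address(rng, po_box=True) if pob else phys
            hh_rows_out[int(hid)] = (codes.KIND_RESIDENTIAL, phys, mail, int(ref_sim), False)

    # GQ-person entities: uniform kind within institutional status.
    gq_entities = entities[~is_hh]
    if len(gq_entities):
        rows = microdata.loc[gq_index[gq_entities - n_households_entities]]
        institutional = rows["institutional_flag"].astype(bool).to_numpy()
        kinds = np.where(
            institutional,
            np.array(codes.INSTITUTIONAL_GQ_CODES)[rng.integers(0, 3, len(rows))],
            np.array(codes.NONINSTITUTIONAL_GQ_CODES)[rng.integers(0, 3, len(rows))],
        )
        unit_ids = np.array([state.gq_units[int(k)] for k in kinds], dtype=np.int64)
        frame = _materialize_vector(
            rows,
            np.full(len(rows), codes.REL_NONE, dtype=np.int8),
            unit_ids,
            shifts[~is_hh],
            start_date,
            rng,
            state,
            ssn_foreign_born_probability,
        )
        sim_frames.append(frame)

    state.simulants = pd.concat(sim_frames)
    state.simulants.index.name = "simulant_id"
    hh_frame = pd.DataFrame.from_dict(
        hh_rows_out,
        orient="index",
        columns=["kind", "physical_address_id", "mailing_address_id", "reference_person_id", "closed"],
    )
    hh_frame.index.name = "household_id"
    state.households = hh_frame.astype(
        {
            "kind": np.int8,
            "physical_address_id": np.int64,
            "mailing_address_id": np.int64,
            "reference_person_id": np.int64,
            "closed": bool,
        }
    )
    return state


def _materialize(
    rows: pd.DataFrame,
    relationship: np.ndarray,
    household_id: int,
    shift: float,
    start_date: dt.date,
    rng: np.random.Generator,
    state: PopulationState,
    ssn_foreign_born_probability: float,
    perturb: bool = True,
) -> pd.DataFrame:
    """Instantiate simulants for one sampled entity."""
    n = len(rows)
    return _materialize_vector(
        rows,
        relationship,
        np.full(n, household_id, dtype=np.int64),
        np.full(n, shift if perturb else np.nan),
        start_date,
        rng,
        state,
        ssn_foreign_born_probability,
    )


def _materialize_vector(
    rows: pd.DataFrame,
    relationship: np.ndarray,
    household_ids: np.ndarray,
    shifts: np.ndarray,
    start_date: dt.date,
    rng: np.random.Generator,
    state: PopulationState,
    ssn_foreign_born_probability: float,
) -> pd.DataFrame:
    """Instantiate simulants for a batch of sampled entities.

    ``shifts`` holds the per-person copy of each entity's shared age shift;
    NaN means "do not perturb" (immigrating entities keep their source ages).
    """
    n = len(rows)
    shifts = np.asarray(shifts, dtype=float)
    precise = rows["age_years"].to_numpy(dtype=float) + rng.random(n)
    perturbable = ~np.isnan(shifts)
    # shift then sign-flip negatives (abs is exactly the flip for shifted values)
    precise = np.where(perturbable, np.abs(precise + np.where(perturbable, shifts, 0.0)), precise)
    ids = state.new_simulant_ids(n)
    foreign = rows["foreign_born_flag"].astype(bool).to_numpy()
    has_ssn = np.where(foreign, rng.random(n) < ssn_foreign_born_probability, True)
    frame = pd.DataFrame(
        {
            "sex": np.where(rows["sex"].to_numpy() == "Male", codes.SEX_MALE, codes.SEX_FEMALE).astype(np.int8),
            "race_ethnicity": map_race_ethnicity_codes(
                rows["race_code"].to_numpy(), rows["hispanic_flag"].to_numpy()
            ),
            "nativity": np.where(foreign, codes.NATIVITY_FOREIGN, codes.NATIVITY_US).astype(np.int8),
            "relationship": relationship.astype(np.int8),
            "household_id": np.asarray(household_ids, dtype=np.int64),
            "has_ssn": has_ssn,
            "employer_id": np.full(n, codes.EMPLOYER_NONE, dtype=np.int64),
            "income_annual": np.zeros(n),
            "status": np.full(n, codes.STATUS_PRESENT, dtype=np.int8),
            "mother_id": np.full(n, -1, dtype=np.int64),
            "date_of_birth": pd.to_datetime(_derive_dob_vector(precise, start_date)),
            "status_date": np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]"),
        },
        index=pd.Index(ids, name="simulant_id"),
    )
    return frame
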