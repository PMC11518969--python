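"""Mortality, fertility, twinning, succession and newborn relationships."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from simpop import codes, demography
from simpop.fixtures import generate_address_lexicon
from simpop.population import initialize_population
from simpop.state import PopulationState

START = dt.date(2019, 1, 1)


def build_household(ages, relationships, sexes=None):
    """Construct a one-household population directly (no microdata)."""
    from simpop.state import AddressRegistry, empty_households, empty_simulants

    n = len(ages)
    sexes = sexes if sexes is not None else [codes.SEX_FEMALE] * n
    lexicon = generate_address_lexicon()
    state = PopulationState(
        simulants=empty_simulants(),
        households=empty_households(),
        addresses=AddressRegistry(lexicon),
    )
    rng = np.random.default_rng(0)
    for kind in codes.GQ_KIND_CODES:
        hid = int(state.new_household_ids(1)[0])
        addr = state.addresses.new_address(rng)
        state.households.loc[hid] = (kind, addr, addr, -1, False)
        state.gq_units[kind] = hid
    hid = int(state.new_household_ids(1)[0])
    addr = state.addresses.new_address(rng)
    ids = state.new_simulant_ids(n)
    ref = [i for i, r in enumerate(relationships) if r == codes.REL_REFERENCE]
    state.households.loc[hid] = (codes.KIND_RESIDENTIAL, addr, addr, ids[ref[0]] if ref else -1, False)
    state.simulants = pd.DataFrame(
        {
            "sex": np.array(sexes, dtype=np.int8),
            "race_ethnicity": np.zeros(n, dtype=np.int8),
            "nativity": np.zeros(n, dtype=np.int8),
            "relationship": np.array(relationships, dtype=np.int8),
            "household_id": np.full(n, hid, dtype=np.int64),
            "has_ssn": np.ones(n, dtype=bool),
            "employer_id": np.full(n, codes.EMPLOYER_NONE, dtype=np.int64),
            "income_annual": np.zeros(n),
            "status": np.zeros(n, dtype=np.int8),
            "mother_id": np.full(n, -1, dtype=np.int64),
            "date_of_birth": [
                pd.Timestamp(START) - pd.Timedelta(days=round(a * 365.25)) for a in ages
            ],
            "status_date": np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]"),
        },
        index=pd.Index(ids, name="simulant_id"),
    )
    return state, hid, ids


class TestMortality:
    def test_zero_rates_kill_nobody(self):
        state, _, _ = build_household([40, 10], [codes.REL_REFERENCE, codes.REL_BIO_CHILD])
        lookup = np.zeros((codes.N_AGE_GROUPS, 2))
        dead = demography.apply_mortality(state, lookup, START, np.random.default_rng(0))
        assert len(dead) == 0

    def test_dead_reference_person_triggers_succession(self):
        state, hid, ids = build_household(
            [70, 44, 17],
            [codes.REL_REFERENCE, codes.REL_BIO_CHILD, codes.REL_GRANDCHILD],
        )
        lookup = np.full((codes.N_AGE_GROUPS, 2), 0.0)
        lookup[codes.age_group_index(70.5), :] = 1e9  # certain death for the 70-year-old
        demography.apply_mortality(state, lookup, START, np.random.default_rng(1))
        assert state.simulants.at[ids[0], "status"] == codes.STATUS_DEAD
        # The 44-year-old (oldest remaining) becomes reference person.
        assert state.simulants.at[ids[1], "relationship"] == codes.REL_REFERENCE
        assert int(state.households.at[hid, "reference_person_id"]) == ids[1]

    def test_missing_stratum_aborts(self):
        state, _, _ = build_household([40], [codes.REL_REFERENCE])
        lookup = np.full((codes.N_AGE_GROUPS, 2), np.nan)
        with pytest.raises(KeyError):
            demography.apply_mortality(state, lookup, START, np.random.default_rng(0))


class TestSuccession:
    def test_single_member_becomes_reference(self):
        state, hid, ids = build_household(
            [50, 20], [codes.REL_REFERENCE, codes.REL_ROOMMATE]
        )
        state.simulants.at[ids[0], "status"] = codes.STATUS_DEAD
        demography.succeed_reference_person(state, hid)
        assert state.simulants.at[ids[1], "relationship"] == codes.REL_REFERENCE

    def test_oldest_remaining_member_wins(self):
        state, hid, ids = build_household(
            [70, 44, 17],
            [codes.REL_REFERENCE, codes.REL_SIBLING, codes.REL_GRANDCHILD],
        )
        state.simulants.at[ids[0], "status"] = codes.STATUS_DEAD
        demography.succeed_reference_person(state, hid)
        assert int(state.households.at[hid, "reference_person_id"]) == ids[1]

    def test_unaccompanied_minor_can_be_reference_person(self):
        state, hid, ids = build_household(
            [40, 17], [codes.REL_REFERENCE, codes.REL_BIO_CHILD]
        )
        state.simulants.at[ids[0], "status"] = codes.STATUS_DEAD
        demography.succeed_reference_person(state, hid)
        assert state.simulants.at[ids[1], "relationship"] == codes.REL_REFERENCE

    def test_sibling_children_of_new_reference(self):
        state, hid, ids = build_household(
            [70, 40, 38],
            [codes.REL_REFERENCE, codes.REL_BIO_CHILD, codes.REL_ADOPTED_CHILD],
        )
        state.simulants.at[ids[0], "status"] = codes.STATUS_DEAD
        demography.succeed_reference_person(state, hid)
        assert state.simulants.at[ids[2], "relationship"] == codes.REL_SIBLING

    def test_empty_household_is_closed_and_address_vacated(self):
        state, hid, ids = build_household([50], [codes.REL_REFERENCE])
        addr = int(state.households.at[hid, "physical_address_id"])
        state.simulants.at[ids[0], "status"] = codes.STATUS_DEAD
        demography.succeed_reference_person(state, hid)
        assert bool(state.households.at[hid, "closed"])
        assert addr in state.addresses.vacated_ids


class TestFertility:
    def _fertile_state(self, n=500):
        ages = [30.0] * n
        rels = [codes.REL_REFERENCE] + [codes.REL_ROOMMATE] * (n - 1)
        return build_household(ages, rels)

    def test_zero_twin_probability_all_singletons(self):
        state, _, _ = self._fertile_state(200)
        lookup = np.full(codes.N_AGE_GROUPS, 5.0)
        births = demography.apply_fertility(
            state, lookup, START, np.random.default_rng(2), twin_probability=0.0
        )
        assert births.n_twin_events == 0
        assert len(births.newborn_ids) == births.n_events

    def test_twin_fraction_matches_configuration(self):
        rng = np.random.default_rng(7)
        state, _, _ = self._fertile_state(600)
        lookup = np.full(codes.N_AGE_GROUPS, 4.0)
        events = twin_events = 0
        date = START
        while events < 10_000:
            births = demography.apply_fertility(state, lookup, date, rng, twin_probability=0.04)
            events += births.n_events
            twin_events += births.n_twin_events
        se3 = 3 * np.sqrt(0.04 * 0.96 / events)
        assert abs(twin_events / events - 0.04) < se3

    def test_newborns_inherit_household_and_race(self):
        state, hid, ids = self._fertile_state(50)
        state.simulants["race_ethnicity"] = codes.RACE_ETHNICITIES.index("Latino")
        lookup = np.full(codes.N_AGE_GROUPS, 10.0)
        births = demography.apply_fertility(state, lookup, START, np.random.default_rng(3))
        assert births.n_events > 0
        babies = state.simulants.loc[births.newborn_ids]
        assert (babies["household_id"] == hid).all()
        assert (babies["race_ethnicity"] == codes.RACE_ETHNICITIES.index("Latino")).all()
        assert (babies["nativity"] == codes.NATIVITY_US).all()
        assert babies["has_ssn"].all()

    def test_twins_share_household_and_date_of_birth(self):
        state, _, _ = self._fertile_state(400)
        lookup = np.full(codes.N_AGE_GROUPS, 5.0)
        births = demography.apply_fertility(
            state, lookup, START, np.random.default_rng(11), twin_probability=1.0
        )
        babies = state.simulants.loc[births.newborn_ids]
        for mother, group in babies.groupby("mother_id"):
            assert group["date_of_birth"].nunique() == 1
            assert group["household_id"].nunique() == 1

    def test_dead_simulants_not_at_risk(self):
        state, _, ids = self._fertile_state(100)
        state.simulants["status"] = codes.STATUS_DEAD
        lookup = np.full(codes.N_AGE_GROUPS, 100.0)
        births = demography.apply_fertility(state, lookup, START, np.random.default_rng(0))
        assert births.n_events == 0

    def test_males_never_give_birth(self):
        state, _, _ = build_household(
            [30] * 100,
            [codes.REL_REFERENCE] + [codes.REL_ROOMMATE] * 99,
            sexes=[codes.SEX_MALE] * 100,
        )
        lookup = np.full(codes.N_AGE_GROUPS, 100.0)
        births = demography.apply_fertility(state, lookup, START, np.random.default_rng(0))
        assert births.n_events == 0


class TestNewbornRelationship:
    @pytest.mark.parametrize(
        "parent,expected",
        [
            (codes.REL_REFERENCE, codes.REL_BIO_CHILD),
            (codes.REL_BIO_CHILD, codes.REL_GRANDCHILD),
            (codes.REL_ADOPTED_CHILD, codes.REL_GRANDCHILD),
            (codes.REL_STEPCHILD, codes.REL_GRANDCHILD),
            (codes.REL_GRANDCHILD, codes.REL_OTHER_RELATIVE),
            (codes.REL_SIBLING, codes.REL_OTHER_RELATIVE),
            (codes.REL_PARENT, codes.REL_OTHER_RELATIVE),
            (codes.REL_PARENT_IN_LAW, codes.REL_OTHER_RELATIVE),
            (codes.REL_CHILD_IN_LAW, codes.REL_OTHER_RELATIVE),
            (codes.REL_OTHER_RELATIVE, codes.REL_OTHER_RELATIVE),
            (codes.REL_ROOMMATE, codes.REL_OTHER_NONRELATIVE),
            (codes.REL_FOSTER_CHILD, codes.REL_OTHER_NONRELATIVE),
            (codes.REL_OTHER_NONRELATIVE, codes.REL_OTHER_NONRELATIVE),
            (codes.REL_NONE, codes.REL_NONE),
        ],
    )
    def test_business_rule_table(self, parent, expected):
        assert demography.newborn_relationship(parent) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            demography.newborn_relationship(99)
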