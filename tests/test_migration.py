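"""Domestic and international migration, and address lifecycle rules."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from simpop import codes, engine, migration
from simpop.fixtures import RateConfig, default_fixtures, generate_address_lexicon
from simpop.population import initialize_population
from simpop.rates import build_lookups
from simpop.state import AddressRegistry

START = dt.date(2019, 1, 1)


@pytest.fixture(scope="module")
def bundle():
    return default_fixtures(seed=21, n_households=400)


def make_state(bundle, n=1000, seed=4):
    return initialize_population(bundle.microdata, n, START, bundle.lexicon, seed=seed)


def zero_rate_lookups(bundle):
    lk = build_lookups(bundle.rates)
    lk.domestic_individual = np.zeros_like(lk.domestic_individual)
    lk.domestic_household = np.zeros_like(lk.domestic_household)
    lk.emigration = np.zeros_like(lk.emigration)
    return lk


class TestDomesticIndividual:
    def test_zero_rates_no_moves(self, bundle):
        state = make_state(bundle)
        lk = zero_rate_lookups(bundle)
        moved = migration.apply_domestic_individual(state, lk, START, np.random.default_rng(0))
        assert moved.individual_moves == 0

    def test_joiners_are_always_other_nonrelative(self, bundle):
        state = make_state(bundle)
        lk = build_lookups(bundle.rates)
        lk.domestic_individual = np.full_like(lk.domestic_individual, 50.0)
        before = state.simulants.copy()
        moved = migration.apply_domestic_individual(
            state,
            lk,
            START,
            np.random.default_rng(1),
            destination_split=(0.0, 1.0, 0.0),
        )
        assert moved.individual_moves > 0
        changed = state.simulants["household_id"] != before["household_id"]
        joined = state.simulants.loc[
            changed & ~state.simulants["household_id"].isin(list(state.gq_units.values()))
        ]
        # A joiner enters as "Other nonrelative"; the only way to hold any
        # other relationship afterwards is succession promoting them to
        # reference person of the household they joined.
        for sim_id, row in joined.iterrows():
            rel = int(row["relationship"])
            if rel == codes.REL_REFERENCE:
                assert int(state.households.at[row["household_id"], "reference_person_id"]) == sim_id
            else:
                assert rel == codes.REL_OTHER_NONRELATIVE

    def test_new_household_movers_become_reference_person(self, bundle):
        state = make_state(bundle, n=300)
        lk = build_lookups(bundle.rates)
        lk.domestic_individual = np.full_like(lk.domestic_individual, 50.0)
        n_households_before = len(state.households)
        migration.apply_domestic_individual(
            state, lk, START, np.random.default_rng(2), destination_split=(1.0, 0.0, 0.0)
        )
        new_hh = state.households.iloc[n_households_before:]
        assert len(new_hh) > 0
        for hid, row in new_hh.iterrows():
            rp = int(row["reference_person_id"])
            assert state.simulants.at[rp, "household_id"] == hid
            assert state.simulants.at[rp, "relationship"] == codes.REL_REFERENCE

    def test_gq_movers_get_gq_kind_and_no_relationship(self, bundle):
        state = make_state(bundle, n=300)
        lk = build_lookups(bundle.rates)
        lk.domestic_individual = np.full_like(lk.domestic_individual, 50.0)
        migration.apply_domestic_individual(
            state, lk, START, np.random.default_rng(3), destination_split=(0.0, 0.0, 1.0)
        )
        in_gq = state.simulants["household_id"].isin(list(state.gq_units.values()))
        assert (state.simulants.loc[in_gq, "relationship"] == codes.REL_NONE).all()

    def test_reference_person_invariant_restored_after_moves(self, bundle):
        state = make_state(bundle)
        lk = build_lookups(bundle.rates)
        lk.domestic_individual = np.full_like(lk.domestic_individual, 20.0)
        migration.apply_domestic_individual(state, lk, START, np.random.default_rng(5))
        sims = state.simulants
        hh = state.households
        for hid in hh.index[(hh["kind"] == codes.KIND_RESIDENTIAL) & ~hh["closed"]]:
            members = state.present_members(hid)
            if len(members):
                assert (sims.loc[members, "relationship"] == codes.REL_REFERENCE).sum() == 1


class TestDomesticHousehold:
    def test_single_person_households_never_move(self, bundle):
        state = make_state(bundle)
        lk = build_lookups(bundle.rates)
        lk.domestic_household = np.full_like(lk.domestic_household, 1e6)
        sims = state.simulants
        counts = sims.loc[state.present_mask(), "household_id"].value_counts()
        singles = set(counts.index[counts == 1])
        addr_before = {
            h: int(state.households.at[h, "physical_address_id"]) for h in singles
        }
        migration.apply_domestic_household(state, lk, START, np.random.default_rng(0))
        for h, addr in addr_before.items():
            assert int(state.households.at[h, "physical_address_id"]) == addr

    def test_relationships_preserved_member_wise(self, bundle):
        state = make_state(bundle)
        lk = build_lookups(bundle.rates)
        lk.domestic_household = np.full_like(lk.domestic_household, 1e6)
        rel_before = state.simulants["relationship"].copy()
        moved = migration.apply_domestic_household(state, lk, START, np.random.default_rng(1))
        assert moved.household_moves > 0
        pd.testing.assert_series_equal(state.simulants["relationship"], rel_before)

    def test_old_address_vacated_and_never_reissued(self, bundle):
        state = make_state(bundle)
        lk = build_lookups(bundle.rates)
        lk.domestic_household = np.full_like(lk.domestic_household, 1e6)
        addr_before = set(state.households["physical_address_id"])
        migration.apply_domestic_household(state, lk, START, np.random.default_rng(2))
        vacated = state.addresses.vacated_ids
        assert vacated
        # Mint many more addresses; none reuses a vacated id.
        rng = np.random.default_rng(3)
        fresh = state.addresses.new_addresses(500, rng)
        assert not (set(fresh) & vacated)


class TestEmigration:
    def test_zero_rates_no_emigration(self, bundle):
        state = make_state(bundle)
        lk = zero_rate_lookups(bundle)
        out = migration.apply_emigration(state, lk, START, np.random.default_rng(0))
        assert out.emigrants == 0

    def test_nonreference_moves_never_remove_reference_person(self, bundle):
        state = make_state(bundle)
        lk = build_lookups(bundle.rates)
        lk.emigration = np.zeros_like(lk.emigration)
        mt = codes.INTERNATIONAL_MOVE_TYPES.index(codes.MOVE_NON_REFERENCE)
        lk.emigration[..., mt] = 1e6  # everyone eligible emigrates via non-ref moves
        out = migration.apply_emigration(state, lk, START, np.random.default_rng(1))
        assert out.emigrants > 0
        gone = state.simulants["status"] == codes.STATUS_EMIGRATED
        assert (state.simulants.loc[gone, "relationship"] != codes.REL_REFERENCE).all()
        # Reference persons all still present: no succession was needed.
        hh = state.households
        open_res = hh[(hh["kind"] == codes.KIND_RESIDENTIAL) & ~hh["closed"]]
        rp_status = state.simulants.loc[open_res["reference_person_id"], "status"]
        assert (rp_status == codes.STATUS_PRESENT).all()

    def test_household_moves_remove_whole_household(self, bundle):
        state = make_state(bundle)
        lk = build_lookups(bundle.rates)
        lk.emigration = np.zeros_like(lk.emigration)
        mt = codes.INTERNATIONAL_MOVE_TYPES.index(codes.MOVE_HOUSEHOLD)
        lk.emigration[..., mt] = 1e6
        migration.apply_emigration(state, lk, START, np.random.default_rng(2))
        hh = state.households
        residential = hh[hh["kind"] == codes.KIND_RESIDENTIAL]
        assert residential["closed"].all()
        in_res = state.simulants["household_id"].isin(residential.index)
        assert (state.simulants.loc[in_res, "status"] == codes.STATUS_EMIGRATED).all()

    def test_emigrated_status_is_permanent_through_engine_run(self, bundle):
        cfg = engine.SimulationConfig(target_population=500, master_seed=9, max_steps=10)
        res = engine.run(cfg, bundle)
        gone = res.state.simulants[res.state.simulants["status"] == codes.STATUS_EMIGRATED]
        for obs in res.observations:
            obs_date = (
                pd.Timestamp(dt.date(obs.date + 1, 1, 1))
                if isinstance(obs.date, int)
                else pd.Timestamp(obs.date)
            )
            bad = gone.index[gone["status_date"] < obs_date]
            assert not set(obs.data["simulant_id"]) & set(bad)


class TestImmigration:
    def test_zero_counts_no_immigrants(self, bundle):
        state = make_state(bundle)
        lk = build_lookups(bundle.rates)
        lk.immigration_events_per_year = {mt: 0.0 for mt in codes.INTERNATIONAL_MOVE_TYPES}
        source = migration.ImmigrationSource(bundle.microdata)
        out = migration.apply_immigration(state, source, lk, START, np.random.default_rng(0))
        assert out.immigrants == 0

    def test_yearly_totals_match_poisson_expectation(self, bundle):
        state = make_state(bundle, n=200)
        lk = build_lookups(bundle.rates)
        lk.immigration_events_per_year = {
            codes.MOVE_HOUSEHOLD: 0.0,
            codes.MOVE_GQ_PERSON: 1000.0,
            codes.MOVE_NON_REFERENCE: 0.0,
        }
        source = migration.ImmigrationSource(bundle.microdata)
        rng = np.random.default_rng(6)
        total = 0
        for step in range(13):  # ~ one year of 28-day steps
            date = START + dt.timedelta(days=28 * step)
            out = migration.apply_immigration(state, source, lk, date, rng)
            total += out.immigrants
        expected = 1000.0 * 13 * 28 / 365.25
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_immigrant_integer_age_matches_source_record(self, bundle):
        # With only GQ-person moves each immigrant is one sampled record whose
        # age must carry over unshifted (floor of precise age == record age).
        state = make_state(bundle, n=100)
        lk = build_lookups(bundle.rates)
        lk.immigration_events_per_year = {
            codes.MOVE_HOUSEHOLD: 0.0,
            codes.MOVE_GQ_PERSON: 4000.0,
            codes.MOVE_NON_REFERENCE: 0.0,
        }
        source = migration.ImmigrationSource(bundle.microdata)
        n_before = len(state.simulants)
        migration.apply_immigration(state, source, lk, START, np.random.default_rng(8))
        new = state.simulants.iloc[n_before:]
        assert len(new) > 0
        ages = np.floor(state.ages_years(START, new.index))
        source_ages = set(bundle.microdata.loc[bundle.microdata["recent_immigrant_flag"], "age_years"])
        assert set(ages.astype(int)) <= source_ages

    def test_positive_counts_with_no_recent_immigrants_aborts(self, bundle):
        micro = bundle.microdata.copy()
        micro["recent_immigrant_flag"] = False
        state = make_state(bundle, n=100)
        lk = build_lookups(bundle.rates)
        lk.immigration_events_per_year = {
            codes.MOVE_HOUSEHOLD: 0.0,
            codes.MOVE_GQ_PERSON: 1e5,
            codes.MOVE_NON_REFERENCE: 0.0,
        }
        source = migration.ImmigrationSource(micro)
        with pytest.raises(RuntimeError):
            migration.apply_immigration(state, source, lk, START, np.random.default_rng(0))


class TestAddressRegistry:
    def test_new_addresses_are_distinct(self):
        reg = AddressRegistry(generate_address_lexicon())
        rng = np.random.default_rng(0)
        ids = reg.new_addresses(10_000, rng)
        assert len(set(ids)) == 10_000

    def test_vacated_id_never_reissued(self):
        reg = AddressRegistry(generate_address_lexicon())
        rng = np.random.default_rng(1)
        first = reg.new_address(rng)
        reg.vacate([first])
        later = reg.new_addresses(200, rng)
        assert first not in set(later)

    def test_empty_lexicon_rejected(self):
        from simpop.fixtures import AddressLexicon

        with pytest.raises(ValueError):
            AddressRegistry(AddressLexicon([], [], [], [], {}))
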