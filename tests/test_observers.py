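"""Observer outputs: schemas, schedules, eligibility rules, ground truth."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from simpop import codes, engine, observers
from simpop.fixtures import default_fixtures
from simpop.observers import CENSUS_COLUMNS, TAX_COLUMNS, WicConfig, floored_age
from simpop.population import initialize_population

START = dt.date(2019, 1, 1)


@pytest.fixture(scope="module")
def bundle():
    return default_fixtures(seed=33, n_households=300)


@pytest.fixture(scope="module")
def result(bundle):
    cfg = engine.SimulationConfig(target_population=800, master_seed=17, max_steps=20)
    cfg.observers.survey_sampling_rate = 0.25
    return engine.run(cfg, bundle)


class TestAges:
    def test_floored_age_matches_calendar(self):
        dob = pd.Series([pd.Timestamp("1993-08-05")])
        assert floored_age(dob, dt.date(2020, 4, 1))[0] == 26
        assert floored_age(dob, dt.date(2020, 8, 5))[0] == 27
        assert floored_age(dob, dt.date(2020, 8, 4))[0] == 26


class TestCensus:
    def test_schema_matches_expected_columns(self, result):
        census = [o for o in result.observations if o.dataset == "census"]
        assert census, "a 2020 census should fall within the run"
        assert list(census[0].data.columns) == CENSUS_COLUMNS

    def test_all_present_simulants_enumerated(self, bundle):
        state = initialize_population(bundle.microdata, 500, START, bundle.lexicon, seed=2)
        table = observers.observe_decennial_census(state, START)
        assert set(table.data["simulant_id"]) == set(state.simulants.index[state.present_mask()])

    def test_dead_simulants_absent(self, bundle):
        state = initialize_population(bundle.microdata, 300, START, bundle.lexicon, seed=3)
        victim = int(state.simulants.index[0])
        state.simulants.at[victim, "status"] = codes.STATUS_DEAD
        table = observers.observe_decennial_census(state, START)
        assert victim not in set(table.data["simulant_id"])

    def test_age_column_is_floored_elapsed_years(self, result):
        census = [o for o in result.observations if o.dataset == "census"][0]
        dob = pd.to_datetime(census.data["date_of_birth"])
        recomputed = floored_age(dob, census.date)
        assert (census.data["age"].to_numpy() == recomputed).all()


class TestSurvey:
    def test_rate_zero_empty(self, bundle, rng):
        state = initialize_population(bundle.microdata, 300, START, bundle.lexicon, seed=4)
        table = observers.observe_household_survey(state, START, 0.0, rng)
        assert table.n_rows == 0

    def test_rate_one_all_present_residential(self, bundle, rng):
        state = initialize_population(bundle.microdata, 300, START, bundle.lexicon, seed=5)
        table = observers.observe_household_survey(state, START, 1.0, rng)
        sims = state.simulants
        residential = ~sims["household_id"].isin(list(state.gq_units.values()))
        expected = set(sims.index[(sims["status"] == codes.STATUS_PRESENT) & residential])
        assert set(table.data["simulant_id"]) == expected

    def test_fixed_seed_identical_sample(self, bundle):
        state = initialize_population(bundle.microdata, 300, START, bundle.lexicon, seed=6)
        a = observers.observe_household_survey(state, START, 0.3, np.random.default_rng(9))
        b = observers.observe_household_survey(state, START, 0.3, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_invalid_rate_rejected(self, bundle, rng):
        state = initialize_population(bundle.microdata, 50, START, bundle.lexicon, seed=7)
        with pytest.raises(ValueError):
            observers.observe_household_survey(state, START, 1.5, rng)


class TestWic:
    def _state_with_incomes(self, bundle, income):
        state = initialize_population(bundle.microdata, 400, START, bundle.lexicon, seed=8)
        state.simulants["income_annual"] = income
        return state

    def test_infinite_threshold_includes_all_eligible(self, bundle):
        state = self._state_with_incomes(bundle, 1e6)
        cfg = WicConfig(income_multiplier=np.inf)
        table = observers.observe_wic(state, 2019, dt.date(2020, 1, 1), cfg)
        ages = state.ages_years(dt.date(2020, 1, 1))
        sims = state.simulants
        residential = ~sims["household_id"].isin(list(state.gq_units.values()))
        n_young = int(((ages < 5.0) & residential & (sims["status"] == 0)).sum())
        assert table.n_rows == n_young  # no birth events: children only

    def test_zero_threshold_empty(self, bundle):
        state = self._state_with_incomes(bundle, 0.0)
        cfg = WicConfig(income_multiplier=0.0)
        table = observers.observe_wic(state, 2019, dt.date(2020, 1, 1), cfg)
        assert table.n_rows == 0

    def test_high_income_household_excluded(self, bundle):
        state = self._state_with_incomes(bundle, 1e9)
        table = observers.observe_wic(state, 2019, dt.date(2020, 1, 1), WicConfig())
        assert table.n_rows == 0

    def test_mothers_with_birth_event_included(self, result):
        wic = [o for o in result.observations if o.dataset == "wic"]
        assert wic
        mothers = wic[0].data[wic[0].data["category"] == "mother"]
        sims = result.state.simulants
        born_that_year = sims[sims["date_of_birth"].dt.year == wic[0].date]
        assert set(mothers["simulant_id"]) <= set(born_that_year["mother_id"])


class TestTax:
    def test_schema(self, result):
        tax = [o for o in result.observations if o.dataset == "tax"]
        assert tax
        assert list(tax[0].data.columns) == TAX_COLUMNS

    def test_one_w2_row_per_stable_employment(self, result):
        tax = [o for o in result.observations if o.dataset == "tax"][0]
        w2 = tax.data[tax.data["tax_form"].isin(["W2", "1099"])]
        stints = result.stints
        year = tax.date
        stable = stints[
            (stints["employer_id"] >= codes.FIRST_REGULAR_EMPLOYER_ID)
            | (stints["employer_id"] == codes.EMPLOYER_MILITARY)
        ]
        # Every W2/1099 row corresponds to a stint and carries a positive wage.
        assert (w2["wages"] >= 0).all()
        assert set(w2["simulant_id"]) <= set(stable["simulant_id"])

    def test_mid_year_job_change_yields_two_rows(self, bundle):
        # Force a deterministic two-stint year through the ledger directly.
        from simpop.employment import StintLedger, initialize_employers

        rng = np.random.default_rng(0)
        reg = initialize_employers(5, rng)
        ids = reg.regular_ids[:2]
        stints = StintLedger()
        stints.open([1], [ids[0]], [40_000.0], dt.date(2020, 1, 1))
        stints.change([1], [ids[1]], [60_000.0], dt.date(2020, 7, 1))
        sims = pd.DataFrame(
            {
                "status": [0],
                "status_date": [pd.NaT],
                "date_of_birth": [pd.Timestamp("1985-02-03")],
                "employer_id": [ids[1]],
                "has_ssn": [True],
            },
            index=pd.Index([1], name="simulant_id"),
        )
        tables = observers.build_tax_tables(
            sims, stints.to_frame(), reg, [2020], dt.date(2021, 6, 1)
        )
        data = tables[0].data
        w2 = data[data["tax_form"] != "1040"]
        assert len(w2) == 2
        assert set(w2["simulant_id"]) == {1}
        assert w2["employer_id"].nunique() == 2
        # Wages prorated by stint fraction of the year.
        assert w2["wages"].sum() == pytest.approx(
            40_000 * (182 / 366) + 60_000 * (184 / 366), rel=0.01
        )

    def test_unemployed_all_year_no_w2_rows(self, bundle):
        from simpop.employment import StintLedger, initialize_employers

        rng = np.random.default_rng(0)
        reg = initialize_employers(5, rng)
        stints = StintLedger()
        stints.open([1], [codes.EMPLOYER_UNEMPLOYED], [0.0], dt.date(2020, 1, 1))
        sims = pd.DataFrame(
            {
                "status": [0],
                "status_date": [pd.NaT],
                "date_of_birth": [pd.Timestamp("1985-02-03")],
                "employer_id": [codes.EMPLOYER_UNEMPLOYED],
                "has_ssn": [False],
            },
            index=pd.Index([1], name="simulant_id"),
        )
        tables = observers.build_tax_tables(
            sims, stints.to_frame(), reg, [2020], dt.date(2021, 6, 1)
        )
        data = tables[0].data
        assert (data["tax_form"] == "1040").all()  # only the return row remains

    def test_ssnless_filers_get_itins(self, result):
        tax = [o for o in result.observations if o.dataset == "tax"]
        for table in tax:
            on_1040 = table.data[table.data["tax_form"] == "1040"]
            assert (on_1040["ssn"].str.len() == 11).all()
            no_ssn = result.state.simulants.loc[on_1040["simulant_id"], "has_ssn"].to_numpy()
            itins = on_1040.loc[~no_ssn, "ssn"]
            assert itins.str.startswith("9").all()


class TestGroundTruthAndExits:
    def test_every_row_carries_true_simulant_id(self, result):
        all_ids = set(result.state.simulants.index)
        for obs in result.observations:
            assert set(obs.data["simulant_id"]) <= all_ids

    def test_no_observation_after_death_or_emigration(self, result):
        sims = result.state.simulants
        exited = sims[sims["status"] != codes.STATUS_PRESENT]
        for obs in result.observations:
            obs_date = (
                pd.Timestamp(dt.date(obs.date + 1, 1, 1))
                if isinstance(obs.date, int)
                else pd.Timestamp(obs.date)
            )
            stale = set(exited.index[exited["status_date"] < obs_date])
            assert not stale & set(obs.data["simulant_id"])

    def test_observer_names_filled(self, result):
        census = [o for o in result.observations if o.dataset == "census"][0]
        assert census.data["first_name"].notna().all()
        assert (census.data["first_name"].str.len() > 0).all()
        assert (census.data["last_name"].str.len() > 0).all()
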