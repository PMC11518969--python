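"""Run loop: clock, component ordering, seeded substreams, event accounting.

The simulation starts at a configurable date (default 2019-01-01) and steps
forward in fixed increments (default 28 days) until the clock strictly
exceeds the end-threshold date (default 2041-05-01), giving 292 steps under
the defaults.  Within each step the components execute in a fixed order —
mortality, fertility, domestic migration (individual then household),
emigration, immigration, employment change — followed by any observers due
in the step's date window.  Each (component, step) pair draws from its own
RNG substream keyed off the master seed, so runs are bit-reproducible and
component event streams are independent of population-size changes.

Every step appends one row to the event log; the accounting identity
``present(t+1) = present(t) + births + immigrants − deaths − emigrants``
holds exactly by construction and is recorded for verification.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import codes, demography, employment, migration, observers
from .engine_utils import num_steps, rate_to_step_probability, substream
from .fixtures import IMMIGRATION_REFERENCE_POPULATION, FixtureSet
from .identity import HyphenationConfig, assign_employer_names, assign_identities
from .population import initialize_population
from .rates import build_lookups
from .state import PopulationState

__all__ = ["SimulationConfig", "SimulationResult", "run", "num_steps", "rate_to_step_probability"]


@dataclass
class ComponentToggles:
    mortality: bool = True
    fertility: bool = True
    domestic_migration: bool = True
    emigration: bool = True
    immigration: bool = True
    employment: bool = True


@dataclass
class ObserverSchedule:
    census: bool = True  # decennial, April 1 of years divisible by 10
    tax: bool = True  # annual, per completed calendar year
    wic: bool = True  # annual, January 1 snapshot covering the prior year
    survey: bool = True
    survey_sampling_rate: float = 0.01
    survey_interval_steps: int = 13  # roughly annual with 28-day steps
    wic_config: observers.WicConfig = field(default_factory=observers.WicConfig)


@dataclass
class SimulationConfig:
    start_date: dt.date = dt.date(2019, 1, 1)
    end_threshold_date: dt.date = dt.date(2041, 5, 1)
    step_days: int = 28
    target_population: int = 10_000
    master_seed: int = 0
    max_steps: int | None = None  # cap the run short of the threshold date
    components: ComponentToggles = field(default_factory=ComponentToggles)
    observers: ObserverSchedule = field(default_factory=ObserverSchedule)
    # demography
    twin_probability: float = 0.04
    # population init
    po_box_probability: float = 0.1
    ssn_foreign_born_probability: float = 0.5
    # migration
    destination_split: tuple[float, float, float] = (0.5, 0.4, 0.1)
    immigration_scale: float | None = None  # default: target_population / reference
    # employment
    n_employers: int = 100
    employment_change_rate: float = 0.5  # 50 changes per 100 person-years
    p_unemployed: float = 0.05
    p_military: float = 0.01
    employer_size_sigma: float = 1.5
    income_base_median: float = 32_000.0
    income_sigma: float = 0.8
    w2_share: float = 0.85
    # identity
    hyphenation_probability: float = 0.05
    max_name_path_length: int = 10

    def __post_init__(self):
        if self.step_days < 1:
            raise ValueError("step_days must be at least 1")
        if self.start_date > self.end_threshold_date:
            raise ValueError("start_date must not exceed end_threshold_date")
        if self.target_population < 1:
            raise ValueError("target_population must be positive")

    def n_steps(self) -> int:
        n = num_steps(self.start_date, self.end_threshold_date, self.step_days)
        return min(n, self.max_steps) if self.max_steps is not None else n

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = dict(raw)
        if "components" in kwargs:
            kwargs["components"] = ComponentToggles(**kwargs["components"])
        if "observers" in kwargs:
            obs = dict(kwargs["observers"])
            if "wic_config" in obs:
                obs["wic_config"] = observers.WicConfig(**obs["wic_config"])
            kwargs["observers"] = ObserverSchedule(**obs)
        for key in ("start_date", "end_threshold_date"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = dt.date.fromisoformat(kwargs[key])
        if "destination_split" in kwargs:
            kwargs["destination_split"] = tuple(kwargs["destination_split"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


EVENT_LOG_COLUMNS = [
    "step",
    "date",
    "present_start",
    "births",
    "twin_births",
    "deaths",
    "individual_moves",
    "household_moves",
    "immigrants",
    "emigrants",
    "immigration_household",
    "immigration_gq_person",
    "immigration_non_reference",
    "emigration_household",
    "emigration_gq_person",
    "emigration_non_reference",
    "employment_changes",
    "move_employment_changes",
    "present_end",
]


@dataclass
class SimulationResult:
    state: PopulationState
    event_log: pd.DataFrame
    observations: list[observers.ObservationTable]
    identity: "pd.DataFrame | None"
    employers: employment.EmployerRegistry
    stints: pd.DataFrame
    config: SimulationConfig


def _census_dates(config: SimulationConfig) -> list[dt.date]:
    return [
        dt.date(year, 4, 1)
        for year in range(config.start_date.year, config.end_threshold_date.year + 2)
        if year % 10 == 0
    ]


def run(config: SimulationConfig, fixtures: FixtureSet, verbose: bool = False) -> SimulationResult:
    """Execute the full pipeline: initialize, step, observe, post-process."""
    seed = config.master_seed
    n_steps = config.n_steps()
    lookups = build_lookups(fixtures.rates)
    step_days = config.step_days

    state = initialize_population(
        fixtures.microdata,
        config.target_population,
        config.start_date,
        fixtures.lexicon,
        substream(seed, "init"),
        po_box_probability=config.po_box_probability,
        ssn_foreign_born_probability=config.ssn_foreign_born_probability,
    )

    emp_rng = substream(seed, "employers")
    registry = employment.initialize_employers(
        config.n_employers,
        emp_rng,
        state.addresses,
        size_sigma=config.employer_size_sigma,
        p_unemployed=config.p_unemployed,
        p_military=config.p_military,
        w2_share=config.w2_share,
    )
    income_model = employment.build_income_model(config.income_base_median, config.income_sigma)
    stints = employment.StintLedger()
    if config.components.employment:
        adults = state.simulants.index[
            state.present_mask() & (state.ages_years(config.start_date) >= codes.WORKING_AGE)
        ].to_numpy()
        employment.assign_initial_employment(
            state.simulants, adults, registry, income_model, stints, config.start_date, emp_rng
        )

    immigration_source = (
        migration.ImmigrationSource(fixtures.microdata) if config.components.immigration else None
    )
    immigration_scale = (
        config.immigration_scale
        if config.immigration_scale is not None
        else config.target_population / IMMIGRATION_REFERENCE_POPULATION
    )

    census_due = _census_dates(config)
    raw_observations: list[observers.ObservationTable] = []
    log_rows = []
    date = config.start_date

    for step in range(n_steps):
        present_start = state.n_present()
        counts = dict.fromkeys(EVENT_LOG_COLUMNS, 0)
        counts["step"], counts["date"], counts["present_start"] = step, date, present_start

        # Simulants at risk of an employment change: those already holding an
        # employment state at the top of the step (new entrants wait a step).
        if config.components.employment:
            sims = state.simulants
            at_risk = sims.index[
                (sims["status"] == codes.STATUS_PRESENT)
                & (sims["employer_id"] != codes.EMPLOYER_NONE)
            ].to_numpy()
        else:
            at_risk = np.array([], dtype=np.int64)

        if config.components.mortality:
            rng = substream(seed, "mortality", step)
            dead = demography.apply_mortality(state, lookups.mortality, date, rng, step_days=step_days)
            counts["deaths"] = len(dead)
            stints.close([s for s in dead], date)

        if config.components.fertility:
            rng = substream(seed, "fertility", step)
            births = demography.apply_fertility(
                state,
                lookups.fertility,
                date,
                rng,
                twin_probability=config.twin_probability,
                step_days=step_days,
            )
            counts["births"] = len(births.newborn_ids)
            counts["twin_births"] = births.n_twin_events

        if config.components.domestic_migration:
            rng = substream(seed, "domestic_individual", step)
            hook = None
            if config.components.employment:
                hook = lambda ids, _rng=rng: employment.force_employment_change(
                    state.simulants, ids, registry, income_model, stints, date, _rng
                )
            moved = migration.apply_domestic_individual(
                state,
                lookups,
                date,
                rng,
                destination_split=config.destination_split,
                step_days=step_days,
                po_box_probability=config.po_box_probability,
                employment_hook=hook,
            )
            counts["individual_moves"] = moved.individual_moves
            counts["move_employment_changes"] += moved.employment_changes

            rng = substream(seed, "domestic_household", step)
            hook = None
            if config.components.employment:
                hook = lambda ids, _rng=rng: employment.force_employment_change(
                    state.simulants, ids, registry, income_model, stints, date, _rng
                )
            hmoved = migration.apply_domestic_household(
                state,
                lookups,
                date,
                rng,
                step_days=step_days,
                po_box_probability=config.po_box_probability,
                employment_hook=hook,
            )
            counts["household_moves"] = hmoved.household_moves
            counts["move_employment_changes"] += hmoved.employment_changes

        if config.components.emigration:
            rng = substream(seed, "emigration", step)
            emi = migration.apply_emigration(state, lookups, date, rng, step_days=step_days)
            counts["emigrants"] = emi.emigrants
            counts["emigration_household"] = emi.emigration_events.get(codes.MOVE_HOUSEHOLD, 0)
            counts["emigration_gq_person"] = emi.emigration_events.get(codes.MOVE_GQ_PERSON, 0)
            counts["emigration_non_reference"] = emi.emigration_events.get(codes.MOVE_NON_REFERENCE, 0)
            if emi.emigrants:
                gone = state.simulants.index[
                    state.simulants["status"] == codes.STATUS_EMIGRATED
                ].to_numpy()
                stints.close(gone, date)

        if config.components.immigration and immigration_source is not None:
            rng = substream(seed, "immigration", step)
            imm = migration.apply_immigration(
                state,
                immigration_source,
                lookups,
                date,
                rng,
                scale=immigration_scale,
                step_days=step_days,
                ssn_foreign_born_probability=config.ssn_foreign_born_probability,
                po_box_probability=config.po_box_probability,
            )
            counts["immigrants"] = imm.immigrants
            counts["immigration_household"] = imm.immigration_events.get(codes.MOVE_HOUSEHOLD, 0)
            counts["immigration_gq_person"] = imm.immigration_events.get(codes.MOVE_GQ_PERSON, 0)
            counts["immigration_non_reference"] = imm.immigration_events.get(codes.MOVE_NON_REFERENCE, 0)

        if config.components.employment:
            rng = substream(seed, "employment", step)
            sims = state.simulants
            still_at_risk = np.intersect1d(
                at_risk,
                sims.index[(sims["status"] == codes.STATUS_PRESENT)].to_numpy(),
                assume_unique=False,
            )
            changed = employment.apply_employment_change(
                sims,
                still_at_risk,
                registry,
                income_model,
                stints,
                date,
                rng,
                change_rate_per_year=config.employment_change_rate,
                step_days=step_days,
            )
            counts["employment_changes"] = len(changed)
            # First-time assignment for simulants who became working-age (or
            # immigrated as adults) — not counted as change events.
            fresh = sims.index[
                (sims["status"] == codes.STATUS_PRESENT)
                & (sims["employer_id"] == codes.EMPLOYER_NONE)
                & (state.ages_years(date) >= codes.WORKING_AGE)
            ].to_numpy()
            employment.assign_initial_employment(
                sims, fresh, registry, income_model, stints, date, rng
            )

        # Observers due within [date, date + step_days).
        window_end = date + dt.timedelta(days=step_days)
        if config.observers.census:
            for cdate in census_due:
                if date <= cdate < window_end:
                    raw_observations.append(observers.observe_decennial_census(state, cdate))
        if config.observers.wic:
            for year in range(config.start_date.year, window_end.year + 1):
                jan1 = dt.date(year, 1, 1)
                if date <= jan1 < window_end and year > config.start_date.year:
                    raw_observations.append(
                        observers.observe_wic(state, year - 1, jan1, config.observers.wic_config)
                    )
        if config.observers.survey and step % config.observers.survey_interval_steps == 0:
            rng = substream(seed, "survey", step)
            raw_observations.append(
                observers.observe_household_survey(
                    state, date, config.observers.survey_sampling_rate, rng
                )
            )

        counts["present_end"] = state.n_present()
        log_rows.append(counts)
        if verbose:
            print(
                f"step {step:4d} {date} present={counts['present_end']:7d} "
                f"births={counts['births']:4d} deaths={counts['deaths']:4d} "
                f"moves={counts['individual_moves'] + counts['household_moves']:4d} "
                f"imm={counts['immigrants']:3d} emi={counts['emigrants']:3d} "
                f"job_changes={counts['employment_changes']:4d}"
            )
        date = date + dt.timedelta(days=step_days)

    event_log = pd.DataFrame(log_rows, columns=EVENT_LOG_COLUMNS)

    # Tax tables are reconstructed from the stint ledger after the run.
    stints_frame = stints.to_frame()
    if config.observers.tax and config.components.employment:
        tax_years = [y for y in range(config.start_date.year, date.year) if dt.date(y + 1, 1, 1) <= date]
        raw_observations.extend(
            observers.build_tax_tables(state.simulants, stints_frame, registry, tax_years, date)
        )

    # Identity post-processing and final observer tables.
    id_rng = substream(seed, "identity")
    registry.table = assign_employer_names(
        registry.table, fixtures.corpus, id_rng, config.max_name_path_length
    )
    identity = assign_identities(
        state.simulants,
        fixtures.names,
        id_rng,
        HyphenationConfig(probability=config.hyphenation_probability),
    )
    final_observations = observers.finalize_observations(
        raw_observations, identity, registry, state.simulants, id_rng
    )

    identity_frame = identity.names.copy()
    identity_frame["ssn"] = identity.ssn
    return SimulationResult(
        state=state,
        event_log=event_log,
        observations=final_observations,
        identity=identity_frame,
        employers=registry,
        stints=stints_frame,
        config=config,
    )
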