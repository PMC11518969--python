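"""Dataset observers: decennial census, tax forms, WIC, household survey.

Each observer emits an :class:`ObservationTable` of rows with the true
simulant id in a dedicated column — the ground truth that makes downstream
entity-resolution evaluation exact.  Observers see only simulants present at
the observation date; the dead and the emigrated never appear in a table
dated after their exit.  Coverage error, noising and nonresponse belong to a
separate corruption layer, not here.

Census and survey rows are captured live during the run (age, relationship
and address are time-varying); tax tables are reconstructed after the run
from the employment-stint ledger.  Names, SSNs/ITINs and employer names are
merged in by the identity post-processing step.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codes
from .employment import EmployerRegistry
from .identity import IdentityTable, itin_registry
from .state import PopulationState

CENSUS_COLUMNS = [
    "simulant_id",
    "first_name",
    "middle_initial",
    "last_name",
    "age",
    "date_of_birth",
    "sex",
    "race_ethnicity",
    "relationship",
    "household_id",
    "household_kind",
    "street_number",
    "street_name",
    "street_suffix",
    "unit",
    "city",
    "state",
    "zip",
]

TAX_COLUMNS = [
    "simulant_id",
    "first_name",
    "last_name",
    "ssn",
    "employer",
    "wages",
    "tax_form",
]


@dataclass
class ObservationTable:
    """One emitted dataset: name, observation date (or tax year), rows."""

    dataset: str
    date: dt.date | int
    data: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def filename(self) -> str:
        year = self.date if isinstance(self.date, int) else self.date.year
        return f"{self.dataset}_{year}.csv"


def floored_age(dob: pd.Series, at: dt.date) -> np.ndarray:
    """Completed years between date of birth and an observation date."""
    at = pd.Timestamp(at)
    years = at.year - dob.dt.year
    before_birthday = (dob.dt.month * 100 + dob.dt.day) > (at.month * 100 + at.day)
    return (years - before_birthday.astype(int)).to_numpy()


def _person_rows(state: PopulationState, ids: np.ndarray, at: dt.date) -> pd.DataFrame:
    """Census-style demographic rows (without identity fields) for ``ids``."""
    sims = state.simulants.loc[ids]
    hh = state.households.loc[sims["household_id"].to_numpy()]
    addr = state.addresses.components_frame(hh["physical_address_id"].to_numpy())
    rel = sims["relationship"].to_numpy()
    frame = pd.DataFrame(
        {
            "simulant_id": sims.index.to_numpy(),
            "age": floored_age(sims["date_of_birth"], at),
            "date_of_birth": sims["date_of_birth"].dt.date.to_numpy(),
            "sex": [codes.SEXES[s] for s in sims["sex"]],
            "race_ethnicity": [codes.RACE_ETHNICITIES[r] for r in sims["race_ethnicity"]],
            "relationship": [codes.RELATIONSHIPS[r] if r >= 0 else "" for r in rel],
            "household_id": sims["household_id"].to_numpy(),
            "household_kind": [codes.HOUSEHOLD_KINDS[k] for k in hh["kind"]],
        }
    )
    for col in ("street_number", "street_name", "street_suffix", "unit", "city", "state", "zip"):
        frame[col] = addr[col].to_numpy()
    return frame


def observe_decennial_census(state: PopulationState, census_date: dt.date) -> ObservationTable:
    """Full enumeration of present simulants (residential and GQ)."""
    ids = state.simulants.index[state.present_mask()].to_numpy()
    return ObservationTable("census", census_date, _person_rows(state, ids, census_date))


def observe_household_survey(
    state: PopulationState,
    date: dt.date,
    sampling_rate: float,
    rng: np.random.Generator,
) -> ObservationTable:
    """Sample residential households independently at ``sampling_rate``."""
    if not 0.0 <= sampling_rate <= 1.0:
        raise ValueError("sampling_rate must be a probability")
    hh = state.households
    candidates = hh.index[(hh["kind"] == codes.KIND_RESIDENTIAL) & ~hh["closed"]].to_numpy()
    sampled = set(candidates[rng.random(len(candidates)) < sampling_rate].tolist())
    sims = state.simulants
    mask = state.present_mask() & sims["household_id"].isin(sampled)
    ids = sims.index[mask].to_numpy()
    return ObservationTable("survey", date, _person_rows(state, ids, date))


@dataclass
class WicConfig:
    """Income-eligibility rule: household income below a multiple of a
    size-dependent guideline; categorical eligibility for women with a birth
    that year and children under an age limit."""

    guideline_base: float = 13_000.0
    guideline_per_member: float = 4_600.0
    income_multiplier: float = 1.85
    child_age_limit: float = 5.0

    def threshold(self, household_size: np.ndarray) -> np.ndarray:
        return self.income_multiplier * (
            self.guideline_base + self.guideline_per_member * (np.asarray(household_size) - 1)
        )


def observe_wic(
    state: PopulationState,
    year: int,
    obs_date: dt.date,
    config: WicConfig | None = None,
) -> ObservationTable:
    """Members of low-income residential households in the eligible categories."""
    config = config or WicConfig()
    sims = state.simulants
    present = state.present_mask()
    hh = state.households
    residential = hh.index[(hh["kind"] == codes.KIND_RESIDENTIAL) & ~hh["closed"]]

    members = sims.loc[present & sims["household_id"].isin(residential)]
    if len(members) == 0:
        return ObservationTable("wic", year, _person_rows(state, np.array([], dtype=np.int64), obs_date))
    grouped = members.groupby("household_id")
    income = grouped["income_annual"].sum()
    size = grouped.size()
    qualifying = income.index[income < config.threshold(size.to_numpy())]

    dob_year = sims["date_of_birth"].dt.year
    mothers_this_year = set(sims.loc[dob_year == year, "mother_id"].to_numpy()) - {-1}
    ages = state.ages_years(obs_date, members.index)
    eligible = members.index[
        (
            members.index.isin(mothers_this_year)
            | (ages < config.child_age_limit)
        )
        & members["household_id"].isin(qualifying)
    ].to_numpy()
    frame = _person_rows(state, eligible, obs_date)
    frame["category"] = np.where(
        np.isin(eligible, list(mothers_this_year)), "mother", "child"
    )
    return ObservationTable("wic", year, frame)


def build_tax_tables(
    simulants: pd.DataFrame,
    stints: pd.DataFrame,
    employers: EmployerRegistry,
    years: list[int],
    run_end: dt.date,
) -> list[ObservationTable]:
    """Reconstruct W2/1099 and 1040 tables per calendar year from the stint ledger.

    One W2/1099 row per employment stint overlapping the year, wages prorated
    linearly by the stint's fraction of the year; unemployed stints produce no
    rows.  One 1040 row per present working-age filer.  Simulants whose
    status changed (death/emigration) before the year-end observation date
    are excluded.
    """
    out = []
    for year in years:
        obs_date = dt.date(year + 1, 1, 1)
        year_start = pd.Timestamp(dt.date(year, 1, 1))
        year_end = pd.Timestamp(dt.date(year + 1, 1, 1))
        days_in_year = (year_end - year_start).days

        alive = simulants["status_date"].isna() | (simulants["status_date"] >= pd.Timestamp(obs_date))
        observable = set(simulants.index[alive])

        s = stints.copy()
        s["end_filled"] = s["end_date"].fillna(pd.Timestamp(run_end))
        overlap_start = s["start_date"].clip(lower=year_start)
        overlap_end = s["end_filled"].clip(upper=year_end)
        overlap_days = (overlap_end - overlap_start).dt.days
        s = s[(overlap_days > 0) & s["simulant_id"].isin(observable)]
        overlap_days = overlap_days[s.index]

        employed = s[s["employer_id"] != codes.EMPLOYER_UNEMPLOYED].copy()
        employed["wages"] = (
            employed["income_annual"] * overlap_days[employed.index] / days_in_year
        ).round(0)
        employed["tax_form"] = employers.tax_form_of(employed["employer_id"].to_numpy())
        w2_rows = employed[["simulant_id", "employer_id", "wages", "tax_form"]].reset_index(drop=True)

        # 1040: one return per working-age filer present at year end.
        ages = (pd.Timestamp(obs_date) - simulants["date_of_birth"]).dt.days / codes.DAYS_PER_YEAR
        filers = simulants.index[
            alive & (ages >= codes.WORKING_AGE) & (simulants["employer_id"] != codes.EMPLOYER_NONE)
        ]
        total_wages = (
            employed.groupby("simulant_id")["wages"].sum().reindex(filers, fill_value=0.0)
        )
        f1040 = pd.DataFrame(
            {
                "simulant_id": filers.to_numpy(),
                "employer_id": codes.EMPLOYER_NONE,
                "wages": total_wages.to_numpy(),
                "tax_form": "1040",
            }
        )
        table = pd.concat([w2_rows, f1040], ignore_index=True)
        out.append(ObservationTable("tax", year, table))
    return out


def finalize_observations(
    observations: list[ObservationTable],
    identity: IdentityTable,
    employers: EmployerRegistry,
    simulants: pd.DataFrame,
    rng: np.random.Generator,
) -> list[ObservationTable]:
    """Merge post-processed identity fields into raw observer tables.

    Census-style tables gain name columns; tax tables gain names, employer
    names, and SSN — or a freshly issued ITIN for SSN-less filers.
    """
    names = identity.names
    employer_names = employers.table["name"].to_dict()
    employer_names[codes.EMPLOYER_MILITARY] = codes.MILITARY_EMPLOYER_NAME
    employer_names[codes.EMPLOYER_UNEMPLOYED] = ""
    employer_names[codes.EMPLOYER_NONE] = ""

    # ITINs for SSN-less simulants appearing on any tax table.
    tax_sims: set[int] = set()
    for obs in observations:
        if obs.dataset == "tax":
            tax_sims.update(obs.data["simulant_id"].tolist())
    needs_itin = [s for s in sorted(tax_sims) if not simulants.at[s, "has_ssn"]]
    itins = itin_registry()
    itin_map = dict(zip(needs_itin, itins.generate_batch(len(needs_itin), rng)))
    identity.itin = pd.Series(itin_map, dtype=object)

    final = []
    for obs in observations:
        frame = obs.data.copy()
        ids = frame["simulant_id"].to_numpy()
        if obs.dataset == "tax":
            frame["first_name"] = names.loc[ids, "first_name"].to_numpy()
            frame["last_name"] = names.loc[ids, "last_name"].to_numpy()
            ssn = identity.ssn.loc[ids].to_numpy(dtype=object)
            blank = ssn == ""
            ssn[blank] = [itin_map.get(int(s), "") for s in ids[blank]]
            frame["ssn"] = ssn
            frame["employer"] = [employer_names.get(int(e), "") for e in frame["employer_id"]]
            frame = frame[TAX_COLUMNS]
        else:
            frame["first_name"] = names.loc[ids, "first_name"].to_numpy()
            frame["middle_initial"] = names.loc[ids, "middle_initial"].to_numpy()
            frame["last_name"] = names.loc[ids, "last_name"].to_numpy()
            ordered = [c for c in CENSUS_COLUMNS if c in frame.columns]
            extras = [c for c in frame.columns if c not in ordered]
            frame = frame[ordered + extras]
        final.append(ObservationTable(obs.dataset, obs.date, frame))
    return final
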