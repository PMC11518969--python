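"""Synthetic calibration inputs for the simulation.

Everything the simulator consumes — household-clustered microdata, stratified
hazard-rate tables, name-frequency tables, a business location-name corpus and
an address lexicon — is generated here programmatically, so the package builds
and tests without any external data.  The tables emulate the *shape* of the
public sources a production run would calibrate from (census microdata with
sampling weights, vital-statistics rate tables, agency name files, a
points-of-interest corpus), not their actual distributions.

Microdata records carry: an opaque household key, integer age, binary sex, a
raw race code plus Hispanic flag (composited later), one of the 13
relationship values for residential members, group-quarters flags, a positive
sampling weight, and nativity / recent-immigrant flags used by the migration
components.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import codes

MICRODATA_COLUMNS = [
    "household_key",
    "person_key",
    "age_years",
    "sex",
    "race_code",
    "hispanic_flag",
    "relationship_code",
    "gq_flag",
    "institutional_flag",
    "weight",
    "foreign_born_flag",
    "recent_immigrant_flag",
]

# Relationship mix for household members beyond the reference person.
_MEMBER_RELATIONSHIPS = (
    "Biological child",
    "Adopted child",
    "Stepchild",
    "Sibling",
    "Parent",
    "Grandchild",
    "Parent-in-law",
    "Child-in-law",
    "Other relative",
    "Roommate",
    "Foster child",
    "Other nonrelative",
)
_MEMBER_REL_WEIGHTS = np.array(
    [0.45, 0.02, 0.04, 0.05, 0.05, 0.05, 0.02, 0.02, 0.08, 0.12, 0.01, 0.09]
)

_RACE_WEIGHTS = np.array([0.60, 0.12, 0.01, 0.06, 0.003, 0.127, 0.04])
_RACE_WEIGHTS = _RACE_WEIGHTS / _RACE_WEIGHTS.sum()


@dataclass
class RateConfig:
    """Base levels for every rate family; rates are deterministic functions of these."""

    mortality_base_rate: float = 1e-4  # per person-year at age 0
    mortality_age_slope: float = 0.085  # Gompertz log-slope per year of age
    mortality_male_factor: float = 1.5
    fertility_scale: float = 1.0
    individual_migration_base: float = 0.12  # moves per person-year
    household_migration_base: float = 0.07  # moves per household-year
    emigration_base: float = 0.002  # events per person-year
    emigration_foreign_born_factor: float = 5.0
    # Immigration events per year, calibrated to a reference population of
    # IMMIGRATION_REFERENCE_POPULATION simulants; the engine scales them.
    immigration_household_events: float = 8.0
    immigration_gq_person_events: float = 3.0
    immigration_non_reference_events: float = 12.0

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"rate config field {name!r} must be non-negative")


IMMIGRATION_REFERENCE_POPULATION = 10_000

# Age-specific fertility shape (births per female-year by 5-year group lower
# bound); roughly a contemporary low-fertility schedule, TFR ~= 1.8.
_FERTILITY_SHAPE = {15: 0.02, 20: 0.07, 25: 0.10, 30: 0.10, 35: 0.05, 40: 0.015, 45: 0.002}

# Domestic-migration age profile (young adults move most).
def _migration_age_factor(age_lo: int) -> float:
    if age_lo < 15:
        return 0.8
    if age_lo < 30:
        return 2.0
    if age_lo < 40:
        return 1.2
    if age_lo < 65:
        return 0.8
    return 0.4


_EMIGRATION_TYPE_WEIGHTS = {
    codes.MOVE_HOUSEHOLD: 0.4,
    codes.MOVE_GQ_PERSON: 0.1,
    codes.MOVE_NON_REFERENCE: 0.5,
}


@dataclass
class RateTableSet:
    """All stratified hazard rates and event counts driving stochastic events."""

    mortality: pd.DataFrame  # age_lo, sex, rate (per person-year)
    fertility: pd.DataFrame  # age_lo, rate (per female-year)
    domestic_individual_migration: pd.DataFrame  # age_lo, sex, race_ethnicity, rate
    domestic_household_migration: pd.DataFrame  # reference-person strata, per household-year
    emigration: pd.DataFrame  # age_lo, sex, race_ethnicity, nativity, state, move_type, rate
    immigration_counts: pd.DataFrame  # move_type, events_per_year (per reference population)

    def validate(self) -> None:
        for name in (
            "mortality",
            "fertility",
            "domestic_individual_migration",
            "domestic_household_migration",
            "emigration",
        ):
            table = getattr(self, name)
            if (table["rate"] < 0).any():
                raise ValueError(f"{name} rates must be non-negative")
        if (self.immigration_counts["events_per_year"] < 0).any():
            raise ValueError("immigration counts must be non-negative")


@dataclass
class NameTables:
    first_names: pd.DataFrame  # sex, decade, name, frequency
    middle_names: pd.DataFrame  # sex, decade, name, frequency
    last_names: pd.DataFrame  # race_ethnicity, name, frequency


@dataclass
class LocationCorpus:
    """Business location-name strings; each a whitespace-separated word sequence."""

    names: list[str]

    def validate(self) -> None:
        if any((not n) or (not n.split()) for n in self.names):
            raise ValueError("corpus names must be non-empty word sequences")


@dataclass
class AddressLexicon:
    street_names: list[str]
    street_suffixes: list[str]
    cities: list[str]
    states: list[str]
    zip_prefixes: dict[str, str]  # state -> leading 3 zip digits


@dataclass
class FixtureSet:
    microdata: pd.DataFrame
    rates: RateTableSet
    names: NameTables
    corpus: LocationCorpus
    lexicon: AddressLexicon
    seed: int
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Microdata


def generate_microdata(
    n_households: int,
    gq_fraction: float = 0.02,
    seed: int = 0,
    *,
    mean_household_size: float = 2.5,
    max_household_size: int = 12,
    foreign_born_fraction: float = 0.14,
    recent_immigrant_fraction: float = 0.01,
) -> pd.DataFrame:
    """Generate household-clustered person microdata.

    Household sizes follow a truncated geometric distribution with the given
    mean, every non-GQ household has exactly one reference person, and an
    additional stream of single-person group-quarters records is appended so
    that roughly ``gq_fraction`` of all persons carry the GQ flag.
    """
    if n_households < 0:
        raise ValueError("n_households must be non-negative")
    if not 0.0 <= gq_fraction <= 1.0:
        raise ValueError("gq_fraction must be a probability")
    if mean_household_size <= 1.0:
        raise ValueError("mean_household_size must exceed 1")
    rng = np.random.default_rng(seed)

    if n_households == 0:
        return pd.DataFrame(columns=MICRODATA_COLUMNS)

    sizes = np.minimum(rng.geometric(1.0 / mean_household_size, n_households), max_household_size)
    n_persons = int(sizes.sum())
    hh_index = np.repeat(np.arange(n_households), sizes)
    member_rank = np.concatenate([np.arange(s) for s in sizes])

    ref_age = rng.integers(18, 91, n_households)
    rel = np.empty(n_persons, dtype=object)
    rel[member_rank == 0] = "Reference person"
    others = member_rank > 0
    rel[others] = rng.choice(_MEMBER_RELATIONSHIPS, others.sum(), p=_MEMBER_REL_WEIGHTS)

    age = np.zeros(n_persons, dtype=np.int64)
    base = ref_age[hh_index]
    age[member_rank == 0] = ref_age
    child_like = others & np.isin(rel, ["Biological child", "Adopted child", "Stepchild", "Foster child"])
    age[child_like] = np.clip(base[child_like] - rng.integers(18, 41, child_like.sum()), 0, None)
    m = others & (rel == "Grandchild")
    age[m] = np.clip(base[m] - rng.integers(40, 61, m.sum()), 0, None)
    m = others & (rel == "Sibling")
    age[m] = np.clip(base[m] + rng.integers(-10, 11, m.sum()), 0, None)
    m = others & np.isin(rel, ["Parent", "Parent-in-law"])
    age[m] = np.clip(base[m] + rng.integers(20, 36, m.sum()), 0, 99)
    m = others & (rel == "Child-in-law")
    age[m] = np.clip(base[m] - rng.integers(16, 35, m.sum()), 18, None)
    m = others & np.isin(rel, ["Roommate", "Other nonrelative"])
    age[m] = rng.integers(18, 66, m.sum())
    m = others & (rel == "Other relative")
    age[m] = rng.integers(0, 91, m.sum())

    # Race/ethnicity correlates within a household.
    hh_race = rng.choice(len(codes.MICRODATA_RACE_CODES), n_households, p=_RACE_WEIGHTS)
    race = hh_race[hh_index].copy()
    resample = rng.random(n_persons) < 0.10
    race[resample] = rng.choice(len(codes.MICRODATA_RACE_CODES), resample.sum(), p=_RACE_WEIGHTS)
    hh_hispanic = rng.random(n_households) < 0.18
    hispanic = hh_hispanic[hh_index]

    sex = rng.choice(["Male", "Female"], n_persons)
    weight_hh = rng.lognormal(3.0, 0.5, n_households)
    gq_flag = np.zeros(n_persons, dtype=bool)
    institutional = np.zeros(n_persons, dtype=bool)
    household_key = np.array([f"H{h:07d}" for h in hh_index])

    frames = {
        "household_key": household_key,
        "age_years": age,
        "sex": sex,
        "race_code": np.array(codes.MICRODATA_RACE_CODES, dtype=object)[race],
        "hispanic_flag": hispanic,
        "relationship_code": rel,
        "gq_flag": gq_flag,
        "institutional_flag": institutional,
        "weight": weight_hh[hh_index],
    }
    table = pd.DataFrame(frames)

    if gq_fraction >= 1.0:
        # Degenerate request: emit every person as an independent GQ record.
        table["relationship_code"] = None
        table["gq_flag"] = True
        table["institutional_flag"] = rng.random(n_persons) < 0.5
        table["household_key"] = [f"G{i:07d}" for i in range(n_persons)]
    elif gq_fraction > 0.0:
        target_total = n_persons / (1.0 - gq_fraction)
        n_gq = int(rng.binomial(int(round(target_total)), gq_fraction))
        if n_gq > 0:
            gq = pd.DataFrame(
                {
                    "household_key": [f"G{i:07d}" for i in range(n_gq)],
                    "age_years": rng.integers(18, 96, n_gq),
                    "sex": rng.choice(["Male", "Female"], n_gq),
                    "race_code": np.array(codes.MICRODATA_RACE_CODES, dtype=object)[
                        rng.choice(len(codes.MICRODATA_RACE_CODES), n_gq, p=_RACE_WEIGHTS)
                    ],
                    "hispanic_flag": rng.random(n_gq) < 0.18,
                    "relationship_code": np.full(n_gq, None, dtype=object),
                    "gq_flag": np.ones(n_gq, dtype=bool),
                    "institutional_flag": rng.random(n_gq) < 0.5,
                    "weight": rng.lognormal(3.0, 0.5, n_gq),
                }
            )
            table = pd.concat([table, gq], ignore_index=True)

    n_total = len(table)
    table["foreign_born_flag"] = rng.random(n_total) < foreign_born_fraction
    recent = np.zeros(n_total, dtype=bool)
    if recent_immigrant_fraction > 0:
        recent = rng.random(n_total) < recent_immigrant_fraction
        table.loc[recent, "foreign_born_flag"] = True
    table["recent_immigrant_flag"] = recent
    table["person_key"] = [f"P{i:08d}" for i in range(n_total)]
    return table[MICRODATA_COLUMNS]


def check_microdata(table: pd.DataFrame) -> None:
    """Raise if a microdata table violates its structural invariants."""
    if len(table) == 0:
        return
    if (table["age_years"] < 0).any():
        raise ValueError("ages must be non-negative")
    if (table["weight"] <= 0).any():
        raise ValueError("weights must be positive")
    gq = table["gq_flag"].astype(bool)
    if table.loc[gq, "relationship_code"].notna().any():
        raise ValueError("GQ records must have no relationship code")
    hh = table.loc[~gq]
    refs = hh[hh["relationship_code"] == "Reference person"].groupby("household_key").size()
    counts = hh.groupby("household_key").size()
    if not refs.reindex(counts.index, fill_value=0).eq(1).all():
        raise ValueError("every non-GQ household needs exactly one reference person")
    unknown = set(hh["relationship_code"].dropna()) - set(codes.RELATIONSHIPS)
    if unknown:
        raise ValueError(f"unknown relationship codes: {unknown}")


# ---------------------------------------------------------------------------
# Rate tables


def generate_rate_tables(config: RateConfig | None = None, seed: int = 0) -> RateTableSet:
    """Build the full stratified rate-table set.

    Rates are deterministic functions of ``config`` — the seed is reserved for
    optional jitter and currently unused — so two calls with different seeds
    return identical tables.
    """
    config = config or RateConfig()
    config.validate()

    age_los = list(codes.AGE_GROUP_LOWER_BOUNDS)
    mids = [lo + 2.5 if lo < 85 else 90.0 for lo in age_los]

    rows = []
    for lo, mid in zip(age_los, mids):
        for sex in codes.SEXES:
            rate = config.mortality_base_rate * np.exp(config.mortality_age_slope * mid)
            if sex == "Male":
                rate *= config.mortality_male_factor
            rows.append((lo, sex, rate))
    mortality = pd.DataFrame(rows, columns=["age_lo", "sex", "rate"])

    fertility = pd.DataFrame(
        {
            "age_lo": age_los,
            "rate": [config.fertility_scale * _FERTILITY_SHAPE.get(lo, 0.0) for lo in age_los],
        }
    )

    rows = []
    for lo in age_los:
        for sex in codes.SEXES:
            for r, race in enumerate(codes.RACE_ETHNICITIES):
                race_factor = 0.91 + 0.03 * r
                rows.append(
                    (lo, sex, race, config.individual_migration_base * _migration_age_factor(lo) * race_factor)
                )
    individual = pd.DataFrame(rows, columns=["age_lo", "sex", "race_ethnicity", "rate"])

    rows = []
    for lo in age_los:
        for sex in codes.SEXES:
            for r, race in enumerate(codes.RACE_ETHNICITIES):
                race_factor = 0.91 + 0.03 * r
                rows.append(
                    (lo, sex, race, config.household_migration_base * _migration_age_factor(lo) * race_factor)
                )
    household = pd.DataFrame(rows, columns=["age_lo", "sex", "race_ethnicity", "rate"])

    lexicon_states = _DEFAULT_STATES
    rows = []
    for lo, sex, race, nativity, state, move_type in product(
        age_los, codes.SEXES, codes.RACE_ETHNICITIES, codes.NATIVITIES, lexicon_states,
        codes.INTERNATIONAL_MOVE_TYPES,
    ):
        rate = config.emigration_base * _EMIGRATION_TYPE_WEIGHTS[move_type]
        if nativity == "Foreign-born":
            rate *= config.emigration_foreign_born_factor
        rows.append((lo, sex, race, nativity, state, move_type, rate))
    emigration = pd.DataFrame(
        rows, columns=["age_lo", "sex", "race_ethnicity", "nativity", "state", "move_type", "rate"]
    )

    immigration = pd.DataFrame(
        {
            "move_type": list(codes.INTERNATIONAL_MOVE_TYPES),
            "events_per_year": [
                config.immigration_household_events,
                config.immigration_gq_person_events,
                config.immigration_non_reference_events,
            ],
        }
    )

    tables = RateTableSet(
        mortality=mortality,
        fertility=fertility,
        domestic_individual_migration=individual,
        domestic_household_migration=household,
        emigration=emigration,
        immigration_counts=immigration,
    )
    tables.validate()
    return tables


# ---------------------------------------------------------------------------
# Names, corpus, address lexicon

_MALE_FIRST = [
    "James", "John", "Robert", "Michael", "William", "David", "Richard", "Joseph",
    "Thomas", "Charles", "Daniel", "Matthew", "Anthony", "Mark", "Steven", "Andrew",
    "Joshua", "Kevin", "Brian", "Jason", "Timothy", "Jose", "Ryan", "Eric", "Jacob",
    "Nathan", "Henry", "Samuel", "Patrick", "Alexander", "Tyler", "Ethan", "Caleb",
    "Logan", "Aiden", "Oscar", "Victor", "Marcus", "Derek", "Jordan",
]
_FEMALE_FIRST = [
    "Mary", "Patricia", "Jennifer", "Linda", "Elizabeth", "Barbara", "Susan",
    "Jessica", "Sarah", "Karen", "Lisa", "Nancy", "Betty", "Margaret", "Sandra",
    "Ashley", "Emily", "Donna", "Michelle", "Carol", "Amanda", "Melissa", "Deborah",
    "Stephanie", "Rebecca", "Laura", "Hannah", "Olivia", "Emma", "Sophia", "Grace",
    "Chloe", "Gail", "Ann", "Melanie", "Erin", "Heather", "Rachel", "Maria", "Gloria",
]
_SURNAMES = [
    "Smith", "Johnson", "Williams", "Brown", "Jones", "Garcia", "Miller", "Davis",
    "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez", "Wilson", "Anderson",
    "Thomas", "Taylor", "Moore", "Jackson", "Martin", "Lee", "Perez", "Thompson",
    "White", "Harris", "Sanchez", "Clark", "Ramirez", "Lewis", "Robinson", "Walker",
    "Young", "Allen", "King", "Wright", "Scott", "Torres", "Nguyen", "Hill", "Flores",
    "Green", "Adams", "Nelson", "Baker", "Hall", "Rivera", "Campbell", "Mitchell",
    "Carter", "Roberts", "Chen", "Kim", "Patel", "Singh", "Begay", "Yazzie",
    "Kealoha", "Mahelona", "Castillo", "Herrera", "Durand", "Molina",
]

NAME_DECADES = tuple(range(1920, 2050, 10))


@dataclass
class NameConfig:
    first_name_floor: int = 5  # minimum frequency kept (privacy-style floor)
    last_name_floor: int = 100
    names_per_stratum: int = 30


def _zipf_table(pool: list[str], n: int, floor: int, rotation: int) -> list[tuple[str, int]]:
    n = min(n, len(pool))
    chosen = [pool[(rotation + i) % len(pool)] for i in range(n)]
    return [(name, floor + round(5000 / (rank + 1))) for rank, name in enumerate(chosen)]


def generate_name_tables(config: NameConfig | None = None, seed: int = 0) -> NameTables:
    """First/middle name frequencies by (sex, birth decade); last names by race/ethnicity.

    Every stratum is non-empty and no frequency falls below the configured
    floor, emulating source files that suppress rare names.
    """
    config = config or NameConfig()
    if config.names_per_stratum <= 0:
        raise ValueError("names_per_stratum must be positive")
    rng = np.random.default_rng(seed)
    offset = int(rng.integers(0, 1000))

    first_rows, middle_rows = [], []
    for sex, pool in (("Male", _MALE_FIRST), ("Female", _FEMALE_FIRST)):
        for d_idx, decade in enumerate(NAME_DECADES):
            for name, freq in _zipf_table(
                pool, config.names_per_stratum, config.first_name_floor, offset + 3 * d_idx
            ):
                first_rows.append((sex, decade, name, freq))
            for name, freq in _zipf_table(
                pool, config.names_per_stratum, config.first_name_floor, offset + 3 * d_idx + 7
            ):
                middle_rows.append((sex, decade, name, freq))

    last_rows = []
    for r_idx, race in enumerate(codes.RACE_ETHNICITIES):
        for name, freq in _zipf_table(
            _SURNAMES, config.names_per_stratum, config.last_name_floor, offset + 7 * r_idx
        ):
            last_rows.append((race, name, freq))

    cols_fm = ["sex", "decade", "name", "frequency"]
    return NameTables(
        first_names=pd.DataFrame(first_rows, columns=cols_fm),
        middle_names=pd.DataFrame(middle_rows, columns=cols_fm),
        last_names=pd.DataFrame(last_rows, columns=["race_ethnicity", "name", "frequency"]),
    )


_CORPUS_OPENERS = [
    "Golden", "Cedar", "Riverside", "Sunset", "Tony's", "Red's", "Blue", "Lakeside",
    "Pikes", "San", "Royal", "Village", "Prairie", "Harbor", "Maple", "Summit",
    "Liberty", "Union", "Mountain", "Nashville",
]
_CORPUS_MIDDLES = [
    "Creek", "Oak", "Valley", "Family", "City", "Garden", "Star", "River", "Stone",
    "Park", "Benito", "Grove", "Hill", "Trail",
]
_CORPUS_CLOSERS = [
    "Cafe", "Supply", "Inc", "Campground", "Clinic", "Market", "Bakery", "Salon",
    "Garage", "Diner", "Books", "Hardware", "Farm", "Studio", "Outfitters",
    "Pharmacy", "Grill", "Brewing", "Co", "Dental",
]


def generate_location_corpus(n_names: int, seed: int = 0) -> LocationCorpus:
    """Generate whitespace-separated business location names from shared word pools."""
    if n_names < 0:
        raise ValueError("n_names must be non-negative")
    rng = np.random.default_rng(seed)
    names = []
    for _ in range(n_names):
        n_words = rng.choice([1, 2, 3, 4], p=[0.1, 0.4, 0.35, 0.15])
        if n_words == 1:
            words = [str(rng.choice(_CORPUS_OPENERS + _CORPUS_CLOSERS))]
        else:
            words = [str(rng.choice(_CORPUS_OPENERS))]
            words += [str(w) for w in rng.choice(_CORPUS_MIDDLES, n_words - 2)]
            words.append(str(rng.choice(_CORPUS_CLOSERS)))
        names.append(" ".join(words))
    corpus = LocationCorpus(names=names)
    corpus.validate()
    return corpus


_STREET_NAMES = [
    "Main", "Oak", "Pine", "Maple", "Cedar", "Elm", "Washington", "Lake", "Hill",
    "Park", "Walnut", "Spring", "North", "Ridge", "Church", "Willow", "Mill",
    "Sunset", "Railroad", "Jackson", "Franklin", "River", "Meadow", "Forest",
    "Highland", "Jefferson", "Madison", "Chestnut", "Spruce", "Birch", "Dogwood",
    "Magnolia", "Juniper", "Sycamore", "Poplar", "Hickory", "Laurel", "Aspen",
    "Cottonwood", "Alder",
]
_STREET_SUFFIXES = ["St", "Ave", "Rd", "Blvd", "Ln", "Dr", "Way", "Ct"]
_CITIES = [
    "Springfield", "Riverton", "Fairview", "Kingston", "Salem", "Greenville",
    "Bristol", "Clinton", "Ashland", "Burlington", "Milton", "Dayton", "Auburn",
    "Clayton", "Lakewood",
]
_DEFAULT_STATES = ["WA", "OR", "CA", "ID", "NV"]
_ZIP_PREFIXES = {"WA": "980", "OR": "972", "CA": "941", "ID": "836", "NV": "891"}


@dataclass
class AddressConfig:
    n_street_names: int = 40
    n_cities: int = 15


def generate_address_lexicon(config: AddressConfig | None = None, seed: int = 0) -> AddressLexicon:
    """Street/city/state component lists used to mint unique synthetic addresses."""
    config = config or AddressConfig()
    if config.n_street_names < 0 or config.n_cities < 0:
        raise ValueError("lexicon sizes must be non-negative")
    rng = np.random.default_rng(seed)
    streets = list(rng.permutation(_STREET_NAMES))[: config.n_street_names]
    cities = list(rng.permutation(_CITIES))[: config.n_cities]
    return AddressLexicon(
        street_names=[str(s) for s in streets],
        street_suffixes=list(_STREET_SUFFIXES),
        cities=[str(c) for c in cities],
        states=list(_DEFAULT_STATES),
        zip_prefixes=dict(_ZIP_PREFIXES),
    )


# ---------------------------------------------------------------------------
# Bundle, serialization


def default_fixtures(
    seed: int = 0,
    n_households: int = 2_000,
    gq_fraction: float = 0.02,
    rate_config: RateConfig | None = None,
    corpus_size: int = 400,
) -> FixtureSet:
    """Generate the complete fixture bundle used by the simulator and tests."""
    config = {
        "n_households": n_households,
        "gq_fraction": gq_fraction,
        "rate_config": asdict(rate_config or RateConfig()),
        "corpus_size": corpus_size,
    }
    return FixtureSet(
        microdata=generate_microdata(n_households, gq_fraction, seed=seed),
        rates=generate_rate_tables(rate_config, seed=seed),
        names=generate_name_tables(seed=seed),
        corpus=generate_location_corpus(corpus_size, seed=seed),
        lexicon=generate_address_lexicon(seed=seed),
        seed=seed,
        config=config,
    )


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_fixtures(fixtures: FixtureSet, out_dir: str | Path) -> Path:
    """Serialize the bundle as one comma-separated UTF-8 file per table plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "microdata.csv": fixtures.microdata,
        "mortality_rates.csv": fixtures.rates.mortality,
        "fertility_rates.csv": fixtures.rates.fertility,
        "domestic_individual_migration_rates.csv": fixtures.rates.domestic_individual_migration,
        "domestic_household_migration_rates.csv": fixtures.rates.domestic_household_migration,
        "emigration_rates.csv": fixtures.rates.emigration,
        "immigration_counts.csv": fixtures.rates.immigration_counts,
        "first_names.csv": fixtures.names.first_names,
        "middle_names.csv": fixtures.names.middle_names,
        "last_names.csv": fixtures.names.last_names,
        "location_names.csv": pd.DataFrame({"name": fixtures.corpus.names}),
        "address_lexicon.csv": pd.DataFrame(
            [("street_name", s, "") for s in fixtures.lexicon.street_names]
            + [("street_suffix", s, "") for s in fixtures.lexicon.street_suffixes]
            + [("city", c, "") for c in fixtures.lexicon.cities]
            + [("state", s, fixtures.lexicon.zip_prefixes[s]) for s in fixtures.lexicon.states],
            columns=["component", "value", "zip_prefix"],
        ),
    }
    for fname, frame in tables.items():
        frame.to_csv(out_dir / fname, index=False)
    manifest = {
        "files": sorted(tables),
        "seed": fixtures.seed,
        "config_hash": config_hash(fixtures.config),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_fixtures(in_dir: str | Path) -> FixtureSet:
    """Load a bundle previously written by :func:`write_fixtures`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    read = lambda f: pd.read_csv(in_dir / f)
    lex = pd.read_csv(in_dir / "address_lexicon.csv", dtype=str).fillna("")
    states = lex.loc[lex["component"] == "state", ["value", "zip_prefix"]]
    lexicon = AddressLexicon(
        street_names=lex.loc[lex["component"] == "street_name", "value"].tolist(),
        street_suffixes=lex.loc[lex["component"] == "street_suffix", "value"].tolist(),
        cities=lex.loc[lex["component"] == "city", "value"].tolist(),
        states=states["value"].tolist(),
        zip_prefixes=dict(zip(states["value"], states["zip_prefix"].astype(str))),
    )
    return FixtureSet(
        microdata=read("microdata.csv"),
        rates=RateTableSet(
            mortality=read("mortality_rates.csv"),
            fertility=read("fertility_rates.csv"),
            domestic_individual_migration=read("domestic_individual_migration_rates.csv"),
            domestic_household_migration=read("domestic_household_migration_rates.csv"),
            emigration=read("emigration_rates.csv"),
            immigration_counts=read("immigration_counts.csv"),
        ),
        names=NameTables(
            first_names=read("first_names.csv"),
            middle_names=read("middle_names.csv"),
            last_names=read("last_names.csv"),
        ),
        corpus=LocationCorpus(names=read("location_names.csv")["name"].tolist()),
        lexicon=lexicon,
        seed=int(manifest["seed"]),
        config={},
    )
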