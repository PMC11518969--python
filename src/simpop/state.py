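"""In-memory population state: simulant table, households, address registry.

The simulant table is a pandas DataFrame indexed by simulant id; categorical
attributes are stored as small integer codes (see :mod:`simpop.codes`).
Addresses are minted by an append-only registry — a vacated address id is
never reissued and no two addresses share the same component tuple.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codes
from .fixtures import AddressLexicon

SIMULANT_DTYPES = {
    "sex": np.int8,
    "race_ethnicity": np.int8,
    "nativity": np.int8,
    "relationship": np.int8,
    "household_id": np.int64,
    "has_ssn": bool,
    "employer_id": np.int64,
    "income_annual": np.float64,
    "status": np.int8,
    "mother_id": np.int64,
}


def empty_simulants() -> pd.DataFrame:
    frame = pd.DataFrame({col: pd.Series(dtype=t) for col, t in SIMULANT_DTYPES.items()})
    frame["date_of_birth"] = pd.Series(dtype="datetime64[ns]")
    frame["status_date"] = pd.Series(dtype="datetime64[ns]")
    frame.index.name = "simulant_id"
    return frame


def empty_households() -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "kind": pd.Series(dtype=np.int8),
            "physical_address_id": pd.Series(dtype=np.int64),
            "mailing_address_id": pd.Series(dtype=np.int64),
            "reference_person_id": pd.Series(dtype=np.int64),
            "closed": pd.Series(dtype=bool),
        }
    )
    frame.index.name = "household_id"
    return frame


class AddressRegistry:
    """Mints globally unique street / PO-box addresses from a component lexicon.

    Ids are sequential and never reused; component tuples are also guaranteed
    unique (collisions are re-drawn, and a clear error is raised if the
    synthetic component space is exhausted).
    """

    _MAX_RETRIES = 200

    def __init__(self, lexicon: AddressLexicon):
        if not lexicon.street_names or not lexicon.cities or not lexicon.states:
            raise ValueError("address lexicon must be non-empty")
        self.lexicon = lexicon
        self._next_id = 0
        self._seen: set[tuple] = set()
        self._vacated: set[int] = set()
        self._rows: dict[str, list] = {
            k: []
            for k in (
                "street_number",
                "street_name",
                "street_suffix",
                "unit",
                "city",
                "state",
                "zip",
                "po_box",
            )
        }

    def __len__(self) -> int:
        return self._next_id

    def _mint(self, rng: np.random.Generator, po_box: bool) -> int:
        lex = self.lexicon
        for _ in range(self._MAX_RETRIES):
            city = str(rng.choice(lex.cities))
            state = str(rng.choice(lex.states))
            zip_code = lex.zip_prefixes.get(state, "990") + f"{rng.integers(0, 100):02d}"
            if po_box:
                number = int(rng.integers(1, 100_000))
                key = ("PO", number, city, state)
                street, suffix, unit = "PO Box", "", ""
            else:
                number = int(rng.integers(1, 20_000))
                street = str(rng.choice(lex.street_names))
                suffix = str(rng.choice(lex.street_suffixes))
                unit = f"Unit {rng.integers(1, 41)}" if rng.random() < 0.25 else ""
                key = (number, street, suffix, unit, city, state)
            if key in self._seen:
                continue
            self._seen.add(key)
            addr_id = self._next_id
            self._next_id += 1
            row = (number, street, suffix, unit, city, state, zip_code, po_box)
            for col, val in zip(self._rows, row):
                self._rows[col].append(val)
            return addr_id
        raise RuntimeError(
            "synthetic address space exhausted: could not mint a unique address"
        )

    def new_address(self, rng: np.random.Generator, po_box: bool = False) -> int:
        return self._mint(rng, po_box)

    def new_addresses(self, n: int, rng: np.random.Generator, po_box: bool = False) -> np.ndarray:
        return np.array([self._mint(rng, po_box) for _ in range(n)], dtype=np.int64)

    def vacate(self, ids) -> None:
        self._vacated.update(int(i) for i in np.atleast_1d(ids))

    @property
    def vacated_ids(self) -> frozenset[int]:
        return frozenset(self._vacated)

    def state_of(self, ids) -> np.ndarray:
        states = np.asarray(self._rows["state"], dtype=object)
        return states[np.asarray(ids, dtype=np.int64)]

    def components_frame(self, ids) -> pd.DataFrame:
        ids = np.asarray(ids, dtype=np.int64)
        frame = pd.DataFrame({col: np.asarray(vals, dtype=object)[ids] for col, vals in self._rows.items()})
        frame.insert(0, "address_id", ids)
        return frame

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self._rows)
        frame.insert(0, "address_id", np.arange(self._next_id, dtype=np.int64))
        frame["vacated"] = frame["address_id"].isin(list(self._vacated))
        return frame


@dataclass
class PopulationState:
    """Complete mutable simulation state."""

    simulants: pd.DataFrame
    households: pd.DataFrame
    addresses: AddressRegistry
    gq_units: dict[int, int] = field(default_factory=dict)  # GQ kind code -> household id
    next_simulant_id: int = 0
    next_household_id: int = 0

    def new_simulant_ids(self, n: int) -> np.ndarray:
        ids = np.arange(self.next_simulant_id, self.next_simulant_id + n, dtype=np.int64)
        self.next_simulant_id += n
        return ids

    def new_household_ids(self, n: int) -> np.ndarray:
        ids = np.arange(self.next_household_id, self.next_household_id + n, dtype=np.int64)
        self.next_household_id += n
        return ids

    # -- views -------------------------------------------------------------

    def present_mask(self) -> pd.Series:
        return self.simulants["status"] == codes.STATUS_PRESENT

    def at_risk_ids(self, date: dt.date) -> np.ndarray:
        """Present simulants exposed to events at a step dated ``date``.

        Simulants born or immigrated mid-step (date of birth / entry after
        the step date) are not at risk until the following step."""
        mask = self.present_mask() & (self.simulants["date_of_birth"] <= pd.Timestamp(date))
        return self.simulants.index[mask].to_numpy()

    def n_present(self) -> int:
        return int(self.present_mask().sum())

    def ages_years(self, date: dt.date, ids=None) -> np.ndarray:
        """Precise ages in years at ``date`` (fractional, from date of birth)."""
        dob = self.simulants["date_of_birth"] if ids is None else self.simulants.loc[ids, "date_of_birth"]
        delta = pd.Timestamp(date) - dob
        return (delta.dt.days / codes.DAYS_PER_YEAR).to_numpy()

    def present_members(self, household_id: int) -> pd.Index:
        sims = self.simulants
        mask = (sims["household_id"] == household_id) & (sims["status"] == codes.STATUS_PRESENT)
        return sims.index[mask]

    def is_gq_household(self, household_id: int) -> bool:
        return int(self.households.at[household_id, "kind"]) != codes.KIND_RESIDENTIAL

    # -- mutations ---------------------------------------------------------

    def close_household(self, household_id: int) -> None:
        """Mark a household closed and vacate its addresses (ids never reused)."""
        hh = self.households
        if bool(hh.at[household_id, "closed"]):
            return
        self.addresses.vacate(
            [int(hh.at[household_id, "physical_address_id"]), int(hh.at[household_id, "mailing_address_id"])]
        )
        hh.at[household_id, "closed"] = True
        hh.at[household_id, "reference_person_id"] = -1
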