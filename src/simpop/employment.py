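"""Employer registry, size-proportional assignment, job-change dynamics, income.

Employers receive an initial size drawn from a heavy-tailed (log-normal)
distribution — a few large employers, many small ones — and simulants are
assigned to an employer with probability proportional to that initial size,
with "unemployed" and a single distinguished military employer included in
the same categorical draw at configurable weights.  Working-age simulants
(18+, including the unemployed) change employment at a configurable hazard;
a change re-runs the same categorical draw, so population-level employer
shares stay proportional to the initial sizes indefinitely.

Wages are log-normal per (age group, sex, race/ethnicity) stratum,
independent of employer, resampled at assignment; the unemployed earn
nothing.  The stratum parameters here are synthetic defaults shaped like a
plausible wage surface, not calibrated to any survey.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codes
from .engine_utils import rate_to_step_probability
from .state import AddressRegistry


@dataclass
class EmployerRegistry:
    """Employers with initial-size weights plus the two distinguished states."""

    table: pd.DataFrame  # indexed by employer_id: initial_size, address_id, tax_form, name
    p_unemployed: float
    p_military: float

    def __post_init__(self):
        if not 0 <= self.p_unemployed + self.p_military < 1:
            raise ValueError("unemployment + military weights must leave room for employers")
        if (self.table["initial_size"] <= 0).any():
            raise ValueError("employer sizes must be positive")

    @property
    def regular_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def assignment_probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """(ids, probabilities) over unemployed, military and regular employers."""
        sizes = self.table["initial_size"].to_numpy(dtype=float)
        p_emp = (1.0 - self.p_unemployed - self.p_military) * sizes / sizes.sum()
        ids = np.concatenate(
            ([codes.EMPLOYER_UNEMPLOYED, codes.EMPLOYER_MILITARY], self.table.index.to_numpy())
        )
        probs = np.concatenate(([self.p_unemployed, self.p_military], p_emp))
        return ids, probs

    def tax_form_of(self, employer_ids: np.ndarray) -> np.ndarray:
        forms = self.table["tax_form"].reindex(employer_ids)
        return forms.fillna("W2").to_numpy()  # military files W2


def initialize_employers(
    n_employers: int,
    rng: np.random.Generator,
    addresses: AddressRegistry | None = None,
    *,
    size_sigma: float = 1.5,
    p_unemployed: float = 0.05,
    p_military: float = 0.01,
    w2_share: float = 0.85,
) -> EmployerRegistry:
    """Create ``n_employers`` regular employers with log-normal initial sizes."""
    if n_employers < 1:
        raise ValueError("need at least one employer")
    ids = np.arange(
        codes.FIRST_REGULAR_EMPLOYER_ID, codes.FIRST_REGULAR_EMPLOYER_ID + n_employers, dtype=np.int64
    )
    sizes = rng.lognormal(mean=0.0, sigma=size_sigma, size=n_employers)
    addr = (
        addresses.new_addresses(n_employers, rng)
        if addresses is not None
        else np.full(n_employers, -1, dtype=np.int64)
    )
    table = pd.DataFrame(
        {
            "initial_size": sizes,
            "address_id": addr,
            "tax_form": np.where(rng.random(n_employers) < w2_share, "W2", "1099"),
            "name": [""] * n_employers,
        },
        index=pd.Index(ids, name="employer_id"),
    )
    return EmployerRegistry(table=table, p_unemployed=p_unemployed, p_military=p_military)


def assign_employer(registry: EmployerRegistry, n: int, rng: np.random.Generator) -> np.ndarray:
    """Categorical draw of employer refs, probability proportional to initial size."""
    ids, probs = registry.assignment_probabilities()
    return rng.choice(ids, size=n, p=probs)


# ---------------------------------------------------------------------------
# Income


@dataclass
class IncomeModel:
    """Log-normal wage parameters per (age group, sex, race/ethnicity)."""

    mu: np.ndarray  # shape (n_age_groups, 2, 7): log median wage
    sigma: np.ndarray  # same shape, > 0

    def __post_init__(self):
        if np.any(self.sigma <= 0):
            raise ValueError("income sigma must be positive")


def build_income_model(base_median: float = 32_000.0, sigma: float = 0.8) -> IncomeModel:
    """Synthetic wage surface: earnings rise to a mid-career peak then decline."""
    age_mid = np.array([lo + 2.5 if lo < 85 else 90.0 for lo in codes.AGE_GROUP_LOWER_BOUNDS])
    profile = 0.45 + 0.85 * np.exp(-(((age_mid - 48.0) / 18.0) ** 2))
    profile[age_mid < 18] = 0.3
    sex_factor = np.array([1.08, 0.95])
    race_factor = 0.94 + 0.02 * np.arange(len(codes.RACE_ETHNICITIES))
    median = base_median * profile[:, None, None] * sex_factor[None, :, None] * race_factor[None, None, :]
    return IncomeModel(mu=np.log(median), sigma=np.full_like(median, sigma))


def sample_income(
    age_group: np.ndarray,
    sex: np.ndarray,
    race: np.ndarray,
    employer_ids: np.ndarray,
    model: IncomeModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Annual wages: zero when unemployed, else a stratum log-normal draw."""
    age_group = np.asarray(age_group, dtype=np.int64)
    if age_group.max(initial=-1) >= model.mu.shape[0]:
        raise KeyError("income model does not cover this age stratum")
    mu = model.mu[age_group, sex, race]
    sigma = model.sigma[age_group, sex, race]
    wages = rng.lognormal(mean=mu, sigma=sigma)
    return np.where(np.asarray(employer_ids) == codes.EMPLOYER_UNEMPLOYED, 0.0, wages)


# ---------------------------------------------------------------------------
# Employment stints


class StintLedger:
    """Append-only record of employment stints (for tax observation).

    One open stint per simulant at a time; a change event closes the current
    stint (even when the re-draw lands on the same employer) and opens a new
    one with freshly sampled income.
    """

    def __init__(self):
        self._sim: list[int] = []
        self._employer: list[int] = []
        self._income: list[float] = []
        self._start: list[np.datetime64] = []
        self._end: list[np.datetime64] = []
        self._open: dict[int, int] = {}

    def open(self, sim_ids, employer_ids, incomes, date: dt.date) -> None:
        d = np.datetime64(date, "D")
        for s, e, inc in zip(np.atleast_1d(sim_ids), np.atleast_1d(employer_ids), np.atleast_1d(incomes)):
            s = int(s)
            if s in self._open:
                raise ValueError(f"simulant {s} already holds an employer")
            self._open[s] = len(self._sim)
            self._sim.append(s)
            self._employer.append(int(e))
            self._income.append(float(inc))
            self._start.append(d)
            self._end.append(np.datetime64("NaT"))

    def close(self, sim_ids, date: dt.date) -> None:
        d = np.datetime64(date, "D")
        for s in np.atleast_1d(sim_ids):
            idx = self._open.pop(int(s), None)
            if idx is not None:
                self._end[idx] = d

    def change(self, sim_ids, employer_ids, incomes, date: dt.date) -> None:
        self.close(sim_ids, date)
        self.open(sim_ids, employer_ids, incomes, date)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "simulant_id": np.array(self._sim, dtype=np.int64),
                "employer_id": np.array(self._employer, dtype=np.int64),
                "income_annual": np.array(self._income, dtype=float),
                "start_date": pd.to_datetime(np.array(self._start, dtype="datetime64[D]")),
                "end_date": pd.to_datetime(np.array(self._end, dtype="datetime64[D]")),
            }
        )


def assign_initial_employment(
    pop: pd.DataFrame,
    sim_ids: np.ndarray,
    registry: EmployerRegistry,
    model: IncomeModel,
    stints: StintLedger,
    date: dt.date,
    rng: np.random.Generator,
) -> None:
    """First-time employer assignment (new adults, immigrants, initialization).

    Uses the same size-proportional draw as change events but does not count
    as a change event.
    """
    if len(sim_ids) == 0:
        return
    employers = assign_employer(registry, len(sim_ids), rng)
    ages = (pd.Timestamp(date) - pop.loc[sim_ids, "date_of_birth"]).dt.days / codes.DAYS_PER_YEAR
    incomes = sample_income(
        codes.age_group_index(ages.to_numpy()),
        pop.loc[sim_ids, "sex"].to_numpy(),
        pop.loc[sim_ids, "race_ethnicity"].to_numpy(),
        employers,
        model,
        rng,
    )
    pop.loc[sim_ids, "employer_id"] = employers
    pop.loc[sim_ids, "income_annual"] = incomes
    stints.open(sim_ids, employers, incomes, date)


def apply_employment_change(
    pop: pd.DataFrame,
    at_risk_ids: np.ndarray,
    registry: EmployerRegistry,
    model: IncomeModel,
    stints: StintLedger,
    date: dt.date,
    rng: np.random.Generator,
    *,
    change_rate_per_year: float = 0.5,
    step_days: int = 28,
) -> np.ndarray:
    """Hazard-driven employment changes; returns the ids that changed.

    Every at-risk simulant changes with the per-step probability implied by
    ``change_rate_per_year``; the new employer may equal the old one (the
    event still counts as a change) and income is resampled.
    """
    if change_rate_per_year < 0:
        raise ValueError("change rate must be non-negative")
    if len(at_risk_ids) == 0:
        return np.array([], dtype=np.int64)
    p = rate_to_step_probability(change_rate_per_year, step_days)
    changed = np.asarray(at_risk_ids)[rng.random(len(at_risk_ids)) < p]
    if len(changed):
        force_employment_change(pop, changed, registry, model, stints, date, rng)
    return changed


def force_employment_change(
    pop: pd.DataFrame,
    sim_ids: np.ndarray,
    registry: EmployerRegistry,
    model: IncomeModel,
    stints: StintLedger,
    date: dt.date,
    rng: np.random.Generator,
) -> None:
    """Resample employer and income for ``sim_ids`` (used by moves and changes)."""
    employers = assign_employer(registry, len(sim_ids), rng)
    ages = (pd.Timestamp(date) - pop.loc[sim_ids, "date_of_birth"]).dt.days / codes.DAYS_PER_YEAR
    incomes = sample_income(
        codes.age_group_index(ages.to_numpy()),
        pop.loc[sim_ids, "sex"].to_numpy(),
        pop.loc[sim_ids, "race_ethnicity"].to_numpy(),
        employers,
        model,
        rng,
    )
    pop.loc[sim_ids, "employer_id"] = employers
    pop.loc[sim_ids, "income_annual"] = incomes
    stints.change(sim_ids, employers, incomes, date)
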