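"""Clock arithmetic, hazard conversion and seeded substreams for the engine."""
from __future__ import annotations

import datetime as dt

import numpy as np

from . import codes

# Fixed component ids keyed into the per-step RNG substreams; independent of
# population size, so runs are reproducible as the population grows.
COMPONENT_KEYS = {
    "init": 0,
    "employers": 1,
    "mortality": 2,
    "fertility": 3,
    "domestic_individual": 4,
    "domestic_household": 5,
    "emigration": 6,
    "immigration": 7,
    "employment": 8,
    "survey": 9,
    "identity": 10,
}


def substream(master_seed: int, component: str, step: int = 0) -> np.random.Generator:
    """Independent RNG stream for one (component, step) pair."""
    return np.random.default_rng([int(master_seed), COMPONENT_KEYS[component], int(step)])


def num_steps(start_date: dt.date, end_threshold_date: dt.date, step_days: int) -> int:
    """Smallest k such that start + k*step_days falls strictly after the threshold.

    The clock runs until it *exceeds* the threshold date, so a run whose start
    equals its threshold still executes one step.
    """
    if step_days < 1:
        raise ValueError("step_days must be positive")
    if end_threshold_date < start_date:
        raise ValueError("end threshold must not precede the start date")
    return (end_threshold_date - start_date).days // step_days + 1


def rate_to_step_probability(rate_per_year: float, step_days: int) -> float:
    """Convert a hazard rate per person-year to a per-step event probability.

    Standard exponential-survival conversion, 1 - exp(-rate * step/365.25);
    monotone in the rate and always in [0, 1).
    """
    if step_days < 1:
        raise ValueError("step_days must be positive")
    rate = np.asarray(rate_per_year, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rates must be non-negative")
    out = -np.expm1(-rate * step_days / codes.DAYS_PER_YEAR)
    out = np.minimum(out, np.nextafter(1.0, 0.0))  # stay strictly below 1
    return float(out) if out.ndim == 0 else out
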