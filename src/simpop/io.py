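"""Delimited-text serialization of population state and observer outputs."""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import codes
from .engine import SimulationResult
from .fixtures import config_hash


def save_population(result: SimulationResult, out_dir: str | Path) -> Path:
    """Write the population state (simulants, households, addresses, employers,
    stints) as comma-separated UTF-8 files; ids are stable across save/load."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sims = result.state.simulants.copy()
    sims["sex"] = [codes.SEXES[s] for s in sims["sex"]]
    sims["race_ethnicity"] = [codes.RACE_ETHNICITIES[r] for r in sims["race_ethnicity"]]
    sims["nativity"] = [codes.NATIVITIES[n] for n in sims["nativity"]]
    sims["relationship"] = [codes.RELATIONSHIPS[r] if r >= 0 else "" for r in sims["relationship"]]
    sims["status"] = [codes.STATUSES[s] for s in sims["status"]]
    if result.identity is not None:
        sims = sims.join(result.identity)
    sims.to_csv(out_dir / "simulants.csv")
    hh = result.state.households.copy()
    hh["kind"] = [codes.HOUSEHOLD_KINDS[k] for k in hh["kind"]]
    hh.to_csv(out_dir / "households.csv")
    result.state.addresses.to_frame().to_csv(out_dir / "addresses.csv", index=False)
    result.employers.table.to_csv(out_dir / "employers.csv")
    result.stints.to_csv(out_dir / "employment_stints.csv", index=False)
    result.event_log.to_csv(out_dir / "event_log.csv", index=False)
    return out_dir


def write_observations(result: SimulationResult, out_dir: str | Path) -> Path:
    """Write each observation table as ``<dataset>_<year>.csv`` plus a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    used_names: dict[str, int] = {}
    for obs in result.observations:
        fname = obs.filename()
        # Surveys can observe the same year more than once.
        if fname in used_names:
            used_names[fname] += 1
            stem, ext = fname.rsplit(".", 1)
            fname = f"{stem}_{used_names[obs.filename()]}.{ext}"
        else:
            used_names[fname] = 0
        obs.data.to_csv(out_dir / fname, index=False)
        entries.append({"dataset": obs.dataset, "date": str(obs.date), "file": fname, "rows": obs.n_rows})
    manifest = {
        "outputs": entries,
        "config_hash": config_hash(result.config.to_dict()),
        "master_seed": result.config.master_seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_population(in_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Load serialized population tables back into DataFrames (ids preserved)."""
    in_dir = Path(in_dir)
    return {
        "simulants": pd.read_csv(in_dir / "simulants.csv", index_col="simulant_id"),
        "households": pd.read_csv(in_dir / "households.csv", index_col="household_id"),
        "addresses": pd.read_csv(in_dir / "addresses.csv"),
        "employers": pd.read_csv(in_dir / "employers.csv", index_col="employer_id"),
        "stints": pd.read_csv(in_dir / "employment_stints.csv"),
        "event_log": pd.read_csv(in_dir / "event_log.csv"),
    }
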