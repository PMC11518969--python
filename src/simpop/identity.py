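"""Identity post-processing: names, SSNs/ITINs, and employer names.

Simulant names are assigned after the dynamic simulation.  First and middle
names are drawn frequency-weighted within (sex, birth-decade) strata; last
names are drawn frequency-weighted by race/ethnicity for simulants sampled
into the population, with a configurable fraction compounded into two-part
(hyphen- or space-joined) surnames.  Simulants born during the simulation
inherit their mother's last name, so twins share a surname.  First and last
names are drawn independently — name correlation is deliberately unmodeled.

SSNs follow the issuing convention: area 001–899 excluding 666, group 01–99,
serial 0001–9999, globally unique.  ITINs use the same shape with a leading
9 and restricted group ranges, and are only issued to tax filers without an
SSN.  Employer names are random walks over a bigram multigraph built from a
location-name corpus, so every adjacent word pair in a generated name occurs
somewhere in the corpus.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import codes
from .fixtures import LocationCorpus, NameTables

START = "<start>"
END = "<end>"

SSN_SPACE_SIZE = 898 * 99 * 9999  # areas (1..899 minus 666) x groups x serials

DEFAULT_ITIN_GROUP_RANGES = ((50, 65), (70, 88), (90, 92), (94, 99))


class IdNumberRegistry:
    """Issues unique 9-digit identifiers rendered "AAA-GG-SSSS"."""

    def __init__(
        self,
        areas: np.ndarray,
        groups: np.ndarray,
        serials: np.ndarray,
        label: str,
    ):
        self._areas = areas
        self._groups = groups
        self._serials = serials
        self._space = len(areas) * len(groups) * len(serials)
        self._issued: set[int] = set()
        self._label = label

    def __len__(self) -> int:
        return len(self._issued)

    @property
    def space_size(self) -> int:
        return self._space

    def generate(self, rng: np.random.Generator) -> str:
        return self.generate_batch(1, rng)[0]

    def generate_batch(self, n: int, rng: np.random.Generator) -> list[str]:
        if len(self._issued) + n > self._space:
            raise RuntimeError(f"{self._label} space exhausted")
        out: list[str] = []
        while len(out) < n:
            m = n - len(out)
            a = rng.choice(self._areas, m)
            g = rng.choice(self._groups, m)
            s = rng.choice(self._serials, m)
            keys = (a.astype(np.int64) * 100 + g) * 10_000 + s
            for key in keys:
                key = int(key)
                if key in self._issued:
                    continue
                self._issued.add(key)
                serial = key % 10_000
                group = (key // 10_000) % 100
                area = key // 1_000_000
                out.append(f"{area:03d}-{group:02d}-{serial:04d}")
                if len(out) == n:
                    break
        return out


def ssn_registry() -> IdNumberRegistry:
    areas = np.setdiff1d(np.arange(1, 900), [666])
    return IdNumberRegistry(areas, np.arange(1, 100), np.arange(1, 10_000), "SSN")


def itin_registry(group_ranges=DEFAULT_ITIN_GROUP_RANGES) -> IdNumberRegistry:
    groups = np.concatenate([np.arange(lo, hi + 1) for lo, hi in group_ranges])
    return IdNumberRegistry(np.arange(900, 1000), groups, np.arange(1, 10_000), "ITIN")


def generate_ssn(registry: IdNumberRegistry, rng: np.random.Generator) -> str:
    """Draw one unique SSN uniformly from the remaining valid space."""
    return registry.generate(rng)


def generate_itin(registry: IdNumberRegistry, rng: np.random.Generator) -> str:
    """Draw one unique ITIN (leading digit 9, restricted group ranges)."""
    return registry.generate(rng)


# ---------------------------------------------------------------------------
# Names


@dataclass
class HyphenationConfig:
    probability: float = 0.05  # chance a sampled surname becomes two-part
    hyphen_share: float = 0.5  # hyphen vs space joiner


def _stratum_sampler(table: pd.DataFrame, keys: list[str]) -> dict:
    out = {}
    for key, group in table.groupby(keys[0] if len(keys) == 1 else keys):
        freq = group["frequency"].to_numpy(dtype=float)
        if len(freq) == 0 or freq.sum() <= 0:
            raise ValueError(f"empty name stratum {key}")
        out[key] = (group["name"].to_numpy(), freq / freq.sum())
    return out


def assign_names(
    simulants: pd.DataFrame,
    tables: NameTables,
    rng: np.random.Generator,
    hyphenation: HyphenationConfig | None = None,
) -> pd.DataFrame:
    """Populate first/middle/last names for every simulant ever created.

    Simulants with a tracked mother inherit her last name (processed in birth
    order, so chains of in-simulation births resolve); everyone else draws a
    surname from their race/ethnicity stratum, possibly compounded.
    """
    hyphenation = hyphenation or HyphenationConfig()
    first_by = _stratum_sampler(tables.first_names, ["sex", "decade"])
    middle_by = _stratum_sampler(tables.middle_names, ["sex", "decade"])
    last_by = _stratum_sampler(tables.last_names, ["race_ethnicity"])

    decades = sorted({d for (_, d) in first_by})
    lo, hi = decades[0], decades[-1]

    n = len(simulants)
    sexes = simulants["sex"].to_numpy()
    birth_decades = np.clip((simulants["date_of_birth"].dt.year // 10 * 10).to_numpy(), lo, hi)
    races = simulants["race_ethnicity"].to_numpy()
    mothers = simulants["mother_id"].to_numpy()

    first = np.empty(n, dtype=object)
    middle = np.empty(n, dtype=object)
    last = np.empty(n, dtype=object)

    for (sex_label, dec), (names, p) in first_by.items():
        mask = (sexes == codes.SEXES.index(sex_label)) & (birth_decades == dec)
        if mask.any():
            first[mask] = rng.choice(names, mask.sum(), p=p)
    for (sex_label, dec), (names, p) in middle_by.items():
        mask = (sexes == codes.SEXES.index(sex_label)) & (birth_decades == dec)
        if mask.any():
            middle[mask] = rng.choice(names, mask.sum(), p=p)
    if any(f is None for f in first) or any(m is None for m in middle):
        raise KeyError("name tables do not cover every (sex, decade) stratum")

    founders = mothers < 0
    for race_label, (names, p) in last_by.items():
        mask = founders & (races == codes.RACE_ETHNICITIES.index(race_label))
        if not mask.any():
            continue
        drawn = rng.choice(names, mask.sum(), p=p).astype(object)
        compound = rng.random(mask.sum()) < hyphenation.probability
        if compound.any():
            second = rng.choice(names, int(compound.sum()), p=p)
            joiners = np.where(
                rng.random(int(compound.sum())) < hyphenation.hyphen_share, "-", " "
            )
            drawn[compound] = [
                f"{a}{j}{b}" for a, b, j in zip(drawn[compound], second, joiners)
            ]
        last[mask] = drawn
    if any(l is None for l in last[founders]):
        raise KeyError("last-name table does not cover every race/ethnicity stratum")

    # Children inherit the mother's surname; process in birth order so
    # grandchildren born in-simulation resolve too.
    index = simulants.index.to_numpy()
    pos = {int(s): i for i, s in enumerate(index)}
    child_order = np.argsort(simulants["date_of_birth"].to_numpy())
    for i in child_order:
        m = int(mothers[i])
        if m >= 0:
            last[i] = last[pos[m]]

    return pd.DataFrame(
        {
            "first_name": first,
            "middle_name": middle,
            "last_name": last,
            "middle_initial": [m[0] if m else "" for m in middle],
        },
        index=simulants.index,
    )


# ---------------------------------------------------------------------------
# Employer names: bigram multigraph random walks


def build_bigram_graph(corpus: LocationCorpus) -> nx.DiGraph:
    """Directed word graph with edge occurrence counts and start/end sentinels.

    The edge count of (u, v) equals the number of times v follows u across
    all corpus names (including <start> -> first word and last word -> <end>),
    so the graph is an aggregated view of the bigram multigraph and every
    corpus name corresponds to a start-to-end path.
    """
    if not corpus.names:
        raise ValueError("cannot build a bigram graph from an empty corpus")
    graph = nx.DiGraph()
    for name in corpus.names:
        words = name.split()
        if not words:
            raise ValueError("corpus contains a blank name")
        path = [START, *words, END]
        for u, v in zip(path, path[1:]):
            if graph.has_edge(u, v):
                graph[u][v]["count"] += 1
            else:
                graph.add_edge(u, v, count=1)
    return graph


def generate_employer_name(
    graph: nx.DiGraph,
    rng: np.random.Generator,
    max_path_length: int = 10,
) -> str:
    """Random walk from <start>, each step uniform over outgoing multi-edges
    (i.e. proportional to edge counts), truncated at ``max_path_length`` words."""
    if max_path_length < 1:
        raise ValueError("max_path_length must be at least 1")
    words: list[str] = []
    node = START
    while len(words) < max_path_length:
        successors = list(graph.successors(node))
        counts = np.array([graph[node][s]["count"] for s in successors], dtype=float)
        node = successors[rng.choice(len(successors), p=counts / counts.sum())]
        if node == END:
            break
        words.append(node)
    return " ".join(words)


def assign_employer_names(
    employers: pd.DataFrame,
    corpus: LocationCorpus,
    rng: np.random.Generator,
    max_path_length: int = 10,
    max_attempts: int = 50,
) -> pd.DataFrame:
    """Fill the employer registry's name column with generated names.

    Names are deduplicated best-effort (regenerated on collision up to
    ``max_attempts``); duplicates beyond that are kept, as real employer
    names also collide.
    """
    graph = build_bigram_graph(corpus)
    seen: set[str] = set()
    names = []
    for _ in range(len(employers)):
        name = generate_employer_name(graph, rng, max_path_length)
        for _ in range(max_attempts):
            if name and name not in seen:
                break
            name = generate_employer_name(graph, rng, max_path_length)
        seen.add(name)
        names.append(name)
    out = employers.copy()
    out["name"] = names
    return out


@dataclass
class IdentityTable:
    """Post-processed identity attributes joined into observer outputs."""

    names: pd.DataFrame  # first/middle/last per simulant
    ssn: pd.Series  # SSN string or "" per simulant
    itin: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))


def assign_identities(
    simulants: pd.DataFrame,
    tables: NameTables,
    rng: np.random.Generator,
    hyphenation: HyphenationConfig | None = None,
) -> IdentityTable:
    """Names for everyone plus SSNs for simulants flagged as holding one."""
    names = assign_names(simulants, tables, rng, hyphenation)
    registry = ssn_registry()
    ssn = pd.Series("", index=simulants.index, dtype=object)
    holders = simulants.index[simulants["has_ssn"]]
    ssn.loc[holders] = registry.generate_batch(len(holders), rng)
    return IdentityTable(names=names, ssn=ssn)
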