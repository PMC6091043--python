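"""Character coding of fungal host specialization and decay mode.

Wood-decay fungi are scored from two ingredients: a host-association
table giving, per fungus species, the number of woody angiosperm and
gymnosperm host species it has been recorded on, and a decay-mode table
(white rot vs brown rot, usually known at genus level). The gymnosperm
association ``g = N_G / (N_G + N_A)`` is thresholded into three host
states (angiosperm specialist / gymnosperm specialist / generalist),
which crossed with the binary decay mode gives a six-state character:

    1 white rot / angiosperm specialist
    2 brown rot / angiosperm specialist
    3 white rot / gymnosperm specialist
    4 brown rot / gymnosperm specialist
    5 white rot / generalist
    6 brown rot / generalist

Odd states are white rot. This fixed ordering is used by every rate
matrix and root prior in :mod:`rotshift.mk_models`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DecayMode",
    "HostState",
    "CodingScheme",
    "SCHEME_90_10",
    "SCHEME_100_0",
    "HostAssociationRecord",
    "DecayModeRecord",
    "SixStateCharacter",
    "StateFrequencies",
    "NoWoodyHostsError",
    "DEFAULT_MIXED_MODE_GENERA",
    "STATE_NAMES",
    "gymnosperm_association",
    "classify_host_state",
    "six_state",
    "state_components",
    "extrapolate_decay_mode",
    "one_genus_subset",
    "summarize_states",
    "code_table",
    "read_hosts_csv",
    "read_decay_csv",
    "write_coded_states",
    "read_coded_states",
]


class DecayMode(str, Enum):
    """Binary wood-decay mode."""

    white = "white"
    brown = "brown"


class HostState(str, Enum):
    """Three-state host preference derived from the gymnosperm association."""

    angiosperm_specialist = "angiosperm_specialist"
    gymnosperm_specialist = "gymnosperm_specialist"
    generalist = "generalist"


@dataclass(frozen=True)
class CodingScheme:
    """Thresholds applied to the gymnosperm association ``g``.

    ``g >= upper_threshold`` codes a gymnosperm specialist and
    ``g <= lower_threshold`` an angiosperm specialist; everything in
    between is a generalist. Both thresholds are inclusive. The
    exclusivity scheme ("100-0") sets ``lower = 0, upper = 1`` so that
    non-exclusive specialists fall into the generalist state.
    """

    lower_threshold: float = 0.10
    upper_threshold: float = 0.90
    name: str = "90-10"

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower_threshold < self.upper_threshold <= 1.0):
            raise ValueError(
                f"invalid thresholds: need 0 <= lower < upper <= 1, got "
                f"({self.lower_threshold}, {self.upper_threshold})"
            )


SCHEME_90_10 = CodingScheme(0.10, 0.90, "90-10")
SCHEME_100_0 = CodingScheme(0.0, 1.0, "100-0")

_SCHEMES = {"90-10": SCHEME_90_10, "100-0": SCHEME_100_0}


def get_scheme(name: str | CodingScheme) -> CodingScheme:
    """Resolve a scheme name ("90-10" or "100-0") to a :class:`CodingScheme`."""
    if isinstance(name, CodingScheme):
        return name
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ValueError(f"unknown coding scheme {name!r}; known: {sorted(_SCHEMES)}")


@dataclass(frozen=True)
class HostAssociationRecord:
    species: str
    n_angiosperm: int
    n_gymnosperm: int

    def __post_init__(self) -> None:
        if self.n_angiosperm < 0 or self.n_gymnosperm < 0:
            raise ValueError(f"negative host count for {self.species}")


@dataclass(frozen=True)
class DecayModeRecord:
    taxon: str
    mode: DecayMode
    source_level: str = "species"  # "genus" or "species"


@dataclass(frozen=True)
class SixStateCharacter:
    species: str
    state: int
    gym_assoc: float

    def __post_init__(self) -> None:
        if self.state not in range(1, 7):
            raise ValueError(f"state must be 1..6, got {self.state}")


class NoWoodyHostsError(ValueError):
    """Raised for a species with no woody angiosperm or gymnosperm hosts."""


#: genera reported with more than one decay mode; extrapolation is unsafe
DEFAULT_MIXED_MODE_GENERA = frozenset({"Clitocybula", "Mucronella", "Hyphoderma"})

#: human-readable names in the fixed 1..6 state order
STATE_NAMES = {
    1: "white/angiosperm-specialist",
    2: "brown/angiosperm-specialist",
    3: "white/gymnosperm-specialist",
    4: "brown/gymnosperm-specialist",
    5: "white/generalist",
    6: "brown/generalist",
}

_STATE_OF = {
    (DecayMode.white, HostState.angiosperm_specialist): 1,
    (DecayMode.brown, HostState.angiosperm_specialist): 2,
    (DecayMode.white, HostState.gymnosperm_specialist): 3,
    (DecayMode.brown, HostState.gymnosperm_specialist): 4,
    (DecayMode.white, HostState.generalist): 5,
    (DecayMode.brown, HostState.generalist): 6,
}
_COMPONENTS_OF = {v: k for k, v in _STATE_OF.items()}


def gymnosperm_association(rec: HostAssociationRecord) -> float:
    """Fraction of woody hosts that are gymnosperms, N_G / (N_G + N_A).

    Raises :class:`NoWoodyHostsError` when both counts are zero; such
    species carry no host information and must be excluded upstream.
    """
    total = rec.n_angiosperm + rec.n_gymnosperm
    if total == 0:
        raise NoWoodyHostsError(f"{rec.species}: no woody angiosperm or gymnosperm hosts")
    return rec.n_gymnosperm / total


def classify_host_state(g: float, scheme: CodingScheme = SCHEME_90_10) -> HostState:
    """Threshold the gymnosperm association into one of three host states."""
    if not (0.0 <= g <= 1.0):
        raise ValueError(f"gymnosperm association must lie in [0, 1], got {g}")
    if g >= scheme.upper_threshold:
        return HostState.gymnosperm_specialist
    if g <= scheme.lower_threshold:
        return HostState.angiosperm_specialist
    return HostState.generalist


def six_state(mode: DecayMode, host: HostState) -> int:
    """Map (decay mode, host state) to the fixed 1..6 state index."""
    return _STATE_OF[(DecayMode(mode), HostState(host))]


def state_components(state: int) -> tuple[DecayMode, HostState]:
    """Inverse of :func:`six_state`."""
    return _COMPONENTS_OF[state]


_NAME_SEP = re.compile(r"[\s_]+")


def genus_of(species: str) -> str:
    """First token of a binomial; whitespace or underscore separated."""
    return _NAME_SEP.split(species.strip())[0]


def binomial_of(species: str) -> str:
    """Canonical 'Genus epithet' key; infraspecific ranks collapse."""
    parts = _NAME_SEP.split(species.strip())
    return " ".join(parts[:2]) if len(parts) >= 2 else species.strip()


def extrapolate_decay_mode(
    genus_table: list[DecayModeRecord],
    species: list[str],
    exceptions: frozenset[str] | set[str] = DEFAULT_MIXED_MODE_GENERA,
) -> list[DecayModeRecord]:
    """Assign each species the decay mode reported for its genus.

    Genera known from the literature to contain both white- and
    brown-rot members (``exceptions``) are unsafe to extrapolate: their
    species are kept only when a species-level record exists. Species
    whose genus has no record at all are dropped with a warning.
    """
    genus_mode = {
        r.taxon: r.mode for r in genus_table if r.source_level == "genus"
    }
    species_mode = {
        binomial_of(r.taxon): r.mode
        for r in genus_table
        if r.source_level == "species"
    }
    out: list[DecayModeRecord] = []
    for sp in species:
        binom = binomial_of(sp)
        genus = genus_of(sp)
        if binom in species_mode:
            out.append(DecayModeRecord(sp, species_mode[binom], "species"))
        elif genus in exceptions:
            logger.warning("dropping %s: genus %s has mixed decay modes", sp, genus)
        elif genus in genus_mode:
            out.append(DecayModeRecord(sp, genus_mode[genus], "genus"))
        else:
            logger.warning("dropping %s: no decay-mode record for genus %s", sp, genus)
    return out


def one_genus_subset(
    table: list[SixStateCharacter], seed: int
) -> list[SixStateCharacter]:
    """Resample exactly one species per genus, uniformly at random.

    Used to measure how robust downstream rate estimates are to the
    genus-level extrapolation of decay mode. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    by_genus: dict[str, list[SixStateCharacter]] = {}
    for ch in table:
        by_genus.setdefault(genus_of(ch.species), []).append(ch)
    out = []
    for genus in sorted(by_genus):
        members = by_genus[genus]
        out.append(members[rng.integers(len(members))])
    return out


@dataclass
class StateFrequencies:
    """Marginal counts/proportions over the six-state coding."""

    n: int
    state_counts: dict[int, int]
    mode_counts: dict[DecayMode, int]
    host_counts: dict[HostState, int]
    state_proportions: dict[int, float] = field(default_factory=dict)
    mode_proportions: dict[DecayMode, float] = field(default_factory=dict)
    host_proportions: dict[HostState, float] = field(default_factory=dict)


def summarize_states(chars: list[SixStateCharacter]) -> StateFrequencies:
    """Count species per six-state, per decay mode and per host state."""
    if not chars:
        raise ValueError("empty character table")
    n = len(chars)
    state_counts = {s: 0 for s in range(1, 7)}
    for ch in chars:
        state_counts[ch.state] += 1
    mode_counts = {m: 0 for m in DecayMode}
    host_counts = {h: 0 for h in HostState}
    for s, c in state_counts.items():
        mode, host = state_components(s)
        mode_counts[mode] += c
        host_counts[host] += c
    return StateFrequencies(
        n=n,
        state_counts=state_counts,
        mode_counts=mode_counts,
        host_counts=host_counts,
        state_proportions={s: c / n for s, c in state_counts.items()},
        mode_proportions={m: c / n for m, c in mode_counts.items()},
        host_proportions={h: c / n for h, c in host_counts.items()},
    )


# ---------------------------------------------------------------------------
# table-level pipeline and CSV interfaces


def code_table(
    hosts: pd.DataFrame,
    decay: list[DecayModeRecord] | pd.DataFrame,
    scheme: CodingScheme = SCHEME_90_10,
    exceptions: frozenset[str] | set[str] = DEFAULT_MIXED_MODE_GENERA,
) -> pd.DataFrame:
    """Code a host-association table into six-state characters.

    Parameters
    ----------
    hosts
        DataFrame with columns ``species, n_angiosperm, n_gymnosperm``.
    decay
        Decay-mode records (or DataFrame with ``taxon, mode, level``),
        genus- or species-level; extrapolated to the species list.
    scheme
        Threshold scheme, default the 90-10 specialization coding.

    Returns
    -------
    DataFrame with columns ``species, state, gym_assoc, mode, host_state``,
    one row per codable species. Species with no woody hosts or no decay
    mode are dropped (with a warning for the latter).
    """
    if hosts["species"].duplicated().any():
        dups = hosts.loc[hosts["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in host table: {dups[:5]}")
    if isinstance(decay, pd.DataFrame):
        decay = _decay_records_from_frame(decay)

    modes = {
        r.taxon: r.mode
        for r in extrapolate_decay_mode(decay, hosts["species"].tolist(), exceptions)
    }
    rows = []
    for rec in hosts.itertuples(index=False):
        r = HostAssociationRecord(rec.species, int(rec.n_angiosperm), int(rec.n_gymnosperm))
        if r.species not in modes:
            continue
        try:
            g = gymnosperm_association(r)
        except NoWoodyHostsError:
            continue
        host = classify_host_state(g, scheme)
        mode = modes[r.species]
        rows.append(
            {
                "species": r.species,
                "state": six_state(mode, host),
                "gym_assoc": g,
                "mode": mode.value,
                "host_state": host.value,
            }
        )
    return pd.DataFrame(rows, columns=["species", "state", "gym_assoc", "mode", "host_state"])


def _decay_records_from_frame(df: pd.DataFrame) -> list[DecayModeRecord]:
    level_col = "level" if "level" in df.columns else "source_level"
    return [
        DecayModeRecord(r.taxon, DecayMode(r.mode), getattr(r, level_col))
        for r in df.itertuples(index=False)
    ]


def read_hosts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species", "n_angiosperm", "n_gymnosperm"}
    if not required.issubset(df.columns):
        raise ValueError(f"hosts CSV must have columns {sorted(required)}")
    return df


def read_decay_csv(path) -> list[DecayModeRecord]:
    df = pd.read_csv(path)
    required = {"taxon", "mode", "level"}
    if not required.issubset(df.columns):
        raise ValueError(f"decay CSV must have columns {sorted(required)}")
    return _decay_records_from_frame(df)


def write_coded_states(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_coded_states(path) -> pd.DataFrame:
    return pd.read_csv(path)


def characters_from_frame(df: pd.DataFrame) -> list[SixStateCharacter]:
    """Convert a coded-states DataFrame to :class:`SixStateCharacter` records."""
    return [
        SixStateCharacter(r.species, int(r.state), float(r.gym_assoc))
        for r in df.itertuples(index=False)
    ]
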