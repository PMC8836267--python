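"""Global computational mutagenesis: ΔΔG, unfolding fractions, foldability.

The screen mirrors a saturation-mutagenesis stability analysis: every residue
is substituted by the 19 alternative amino acids, each substitution gets a
destabilization free energy ΔΔG (kcal/mol, positive = destabilizing), the
ΔΔG is standardized to a [0, 1] *unfolding fraction* by the two-state
Boltzmann occupancy

    f(ΔΔG) = 1 / (1 + exp(-ΔΔG / RT)),

and the per-residue *foldability* is the severity-weighted sum of the 19
unfolding fractions (maximum 19 under unit weights).  Residues whose
foldability reaches the critical threshold are flagged as critical for the
protein's thermodynamic stability.

ΔΔG values can come from the transparent built-in engine below or be imported
from an external table (e.g. values computed by a semi-empirical force
field).  The built-in engine is a deterministic, orderable surrogate scoring
function, not a re-implementation of any published potential; its terms are
hydrophobic burial mismatch, packing-volume change, disulfide-bridge loss,
glycine-flexibility loss and proline introduction, each scaled by burial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import expit

from .disulfide import DisulfideBridge, detect_disulfides
from .mutation import AA_ALPHABET, MutationSpec
from .structure import Residue, Structure, THREE_TO_ONE

__all__ = [
    "MutationSpec",
    "ScreenConfig",
    "StabilityRecord",
    "FoldabilityMap",
    "ddg_estimate",
    "unfolding_fraction",
    "foldability",
    "foldability_from_records",
    "screen_all",
    "report_table",
    "import_ddg_table",
    "GAS_CONSTANT_KCAL",
]

#: Gas constant in kcal/(mol·K).
GAS_CONSTANT_KCAL = 0.0019872

#: Kyte-Doolittle hydropathy index.
KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Residue van-der-Waals volumes, Å³ (standard side-chain volume table).
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}

# built-in engine coefficients (kcal/mol) and normalizers
C_HYDROPATHY = 2.0
C_VOLUME = 2.0
C_DISULFIDE = 4.0
C_GLYCINE = 2.0
C_PROLINE = 2.5
DELTA_H_MAX = 9.0
DELTA_V_MAX = 120.0
BURIAL_RADIUS = 10.0
BURIAL_NORM = 20

#: Default foldability threshold for the critical flag.  The bridge-loss term
#: alone bounds a bridge-forming Cys from below at 19·f(4.0) ≈ 18.978, while
#: the remaining terms bound any residue without a bridge from above below
#: ~18.9 even at full burial; 18.95 sits between those closed-form bounds.
DEFAULT_CRITICAL_THRESHOLD = 18.95


class WildTypeMismatchError(ValueError):
    """Raised when a mutation's wild-type letter disagrees with the structure."""


@dataclass
class ScreenConfig:
    """Parameters of the stability screen.

    ``weights`` maps a substitution class to a severity weight in [0, 1];
    keys may be a full substitution ("CS" for Cys→Ser) or a mutant letter
    ("S"); anything unmatched defaults to 1, which makes the foldability
    ceiling exactly 19.
    """

    temperature: float = 298.15
    transform: str = "boltzmann"
    weights: Mapping[str, float] = field(default_factory=dict)
    engine: str = "builtin"
    critical_threshold: float = DEFAULT_CRITICAL_THRESHOLD
    ddg_table: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.transform != "boltzmann":
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.engine not in ("builtin", "table"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.engine == "table" and self.ddg_table is None:
            raise ValueError("engine='table' requires a ddg_table")

    @property
    def rt(self) -> float:
        """RT in kcal/mol."""
        return GAS_CONSTANT_KCAL * self.temperature

    def weight_for(self, wt: str, mut: str) -> float:
        for key in (f"{wt}{mut}", mut):
            if key in self.weights:
                return float(self.weights[key])
        return 1.0


@dataclass
class StabilityRecord:
    """One substitution with its ΔΔG, unfolding fraction and severity weight."""

    mutation: MutationSpec
    ddg: float
    unfolding: float
    weight: float = 1.0


@dataclass
class ResidueScreen:
    """Screen result for one residue: 19 records plus the aggregate."""

    chain: str
    number: int
    icode: str
    name: str
    foldability: float
    critical: bool
    records: list[StabilityRecord]


@dataclass
class FoldabilityMap:
    """Per-residue foldability values in [0, 19] with criticality flags."""

    entries: list[ResidueScreen]
    config: ScreenConfig

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, number: int, chain: str | None = None) -> ResidueScreen:
        for e in self.entries:
            if e.number == number and (chain is None or e.chain == chain):
                return e
        raise KeyError(f"no screened residue {number}")

    def foldability_of(self, number: int, chain: str | None = None) -> float:
        return self.entry(number, chain).foldability

    def critical_residues(self) -> list[int]:
        """Numbers of critical residues, in residue-number order."""
        return sorted(e.number for e in self.entries if e.critical)

    def scores(self) -> dict[tuple[str, int], float]:
        """Per-residue foldability keyed for B-factor export."""
        return {(e.chain, e.number): e.foldability for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chain": e.chain,
                    "residue": e.number,
                    "name": e.name,
                    "foldability": e.foldability,
                    "critical": e.critical,
                }
                for e in self.entries
            ],
            columns=["chain", "residue", "name", "foldability", "critical"],
        )


# ---------------------------------------------------------------------------
# standardization

def unfolding_fraction(ddg: float, config: ScreenConfig | None = None) -> float:
    """Two-state Boltzmann standardization of ΔΔG to the unfolded fraction.

    f(ΔΔG) = 1/(1+exp(-ΔΔG/RT)); strictly increasing, f(0) = 0.5, and
    f(x) + f(-x) = 1.
    """
    config = config or ScreenConfig()
    return float(expit(ddg / config.rt))


# ---------------------------------------------------------------------------
# built-in ΔΔG engine

def _burial(structure: Structure, residue: Residue) -> float:
    """Burial factor B = min(1, N10/20).

    N10 counts the other amino-acid residues with any heavy atom within 10 Å
    of this residue's CB (CA for Gly or when CB is absent).
    """
    anchor_name = "CB" if residue.has_atom("CB") else "CA"
    anchor = residue.atom(anchor_name).coords[None, :]
    n = 0
    for other in structure.residues:
        if not other.is_amino or other.id == residue.id:
            continue
        coords = other.heavy_coords()
        if len(coords) and cdist(anchor, coords).min() <= BURIAL_RADIUS:
            n += 1
    return min(1.0, n / BURIAL_NORM)


def _engine_terms(wt: str, mut: str, burial: float, n_broken: int) -> float:
    """The built-in scoring function, given precomputed burial and bridge loss."""
    hydro = max(0.0, (KD_HYDROPATHY[wt] - KD_HYDROPATHY[mut]) / DELTA_H_MAX)
    volume = abs(RESIDUE_VOLUME[mut] - RESIDUE_VOLUME[wt]) / DELTA_V_MAX
    ddg = (
        C_HYDROPATHY * burial * hydro
        + C_VOLUME * burial * volume
        + C_DISULFIDE * n_broken
        + (C_GLYCINE * burial if wt == "G" else 0.0)
        + (C_PROLINE * burial if mut == "P" else 0.0)
    )
    return float(ddg)


def ddg_estimate(structure: Structure, mutation: MutationSpec,
                 bridges: Sequence[DisulfideBridge] | None = None,
                 config: ScreenConfig | None = None,
                 chain: str | None = None) -> float:
    """Destabilization free energy of one substitution, kcal/mol.

    Deterministic; identity substitutions score exactly 0.  With
    ``config.engine == "table"`` the value is looked up in the imported table
    instead of being computed.
    """
    config = config or ScreenConfig()
    residue = structure.get_residue(mutation.position, chain=chain)
    if not residue.is_amino:
        raise ValueError(f"residue {mutation.position} ({residue.name}) is not a standard amino acid")
    if THREE_TO_ONE[residue.name] != mutation.wt:
        raise WildTypeMismatchError(
            f"residue {mutation.position} is {residue.name}; mutation {mutation} "
            f"expects {mutation.wt}"
        )
    if mutation.is_identity:
        return 0.0
    if config.engine == "table":
        key = str(mutation)
        table = config.ddg_table or {}
        if key not in table:
            raise KeyError(f"mutation {key} not present in the imported ΔΔG table")
        return float(table[key])
    if bridges is None:
        bridges = detect_disulfides(structure)
    n_broken = 0
    if mutation.wt == "C" and mutation.mut != "C":
        n_broken = sum(1 for b in bridges if b.involves(mutation.position))
    return _engine_terms(mutation.wt, mutation.mut,
                         _burial(structure, residue), n_broken)


# ---------------------------------------------------------------------------
# foldability

def foldability_from_records(records: Iterable[StabilityRecord]) -> float:
    """Severity-weighted sum of unfolding fractions — the foldability value."""
    return float(sum(r.weight * r.unfolding for r in records))


def screen_residue(structure: Structure, residue: Residue,
                   config: ScreenConfig,
                   bridges: Sequence[DisulfideBridge]) -> list[StabilityRecord]:
    """The 19 substitution records for one residue."""
    wt = THREE_TO_ONE[residue.name]
    if config.engine == "builtin":
        burial = _burial(structure, residue)
        n_broken = sum(1 for b in bridges if b.involves(residue.number)) if wt == "C" else 0
    records = []
    for mut in AA_ALPHABET:
        if mut == wt:
            continue
        spec = MutationSpec(residue.number, wt, mut)
        if config.engine == "builtin":
            ddg = _engine_terms(wt, mut, burial, n_broken)
        else:
            ddg = ddg_estimate(structure, spec, bridges=bridges, config=config,
                               chain=residue.chain)
        records.append(
            StabilityRecord(
                mutation=spec,
                ddg=ddg,
                unfolding=unfolding_fraction(ddg, config),
                weight=config.weight_for(wt, mut),
            )
        )
    return records


def foldability(structure: Structure, position: int,
                config: ScreenConfig | None = None,
                bridges: Sequence[DisulfideBridge] | None = None,
                chain: str | None = None) -> float:
    """Foldability of one residue: Σ weight × unfolding over 19 substitutions."""
    config = config or ScreenConfig()
    residue = structure.get_residue(position, chain=chain)
    if not residue.is_amino:
        raise ValueError(f"residue {position} ({residue.name}) is not a standard amino acid")
    if bridges is None:
        bridges = detect_disulfides(structure)
    return foldability_from_records(screen_residue(structure, residue, config, bridges))


def screen_all(structure: Structure,
               config: ScreenConfig | None = None) -> FoldabilityMap:
    """Saturation screen over every standard residue in the structure."""
    config = config or ScreenConfig()
    amino = structure.amino_residues()
    if not amino:
        raise ValueError("structure contains no standard amino-acid residues")
    bridges = detect_disulfides(structure)
    entries = []
    for residue in amino:
        records = screen_residue(structure, residue, config, bridges)
        value = foldability_from_records(records)
        entries.append(
            ResidueScreen(
                chain=residue.chain,
                number=residue.number,
                icode=residue.icode,
                name=residue.name,
                foldability=value,
                critical=value >= config.critical_threshold,
                records=records,
            )
        )
    return FoldabilityMap(entries=entries, config=config)


# ---------------------------------------------------------------------------
# reporting and ΔΔG import

REPORT_COLUMNS = ["mutation", "unfolding_fraction", "foldability", "ddg_kcal_mol"]


def report_table(fmap: FoldabilityMap,
                 mutations: Sequence[MutationSpec]) -> pd.DataFrame:
    """Per-mutation report: unfolding fraction, residue foldability, ΔΔG."""
    rows = []
    for spec in mutations:
        entry = fmap.entry(spec.position)
        record = next((r for r in entry.records
                       if r.mutation.wt == spec.wt and r.mutation.mut == spec.mut), None)
        if record is None:
            raise KeyError(f"mutation {spec} not found in the screen "
                           f"(residue {spec.position} is {entry.name})")
        rows.append(
            {
                "mutation": str(spec),
                "unfolding_fraction": record.unfolding,
                "foldability": entry.foldability,
                "ddg_kcal_mol": record.ddg,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def import_ddg_table(path: str | Path) -> dict[str, float]:
    """Read an external two-column (mutation, ddg) delimited table.

    Lets externally computed ΔΔG values (e.g. from a semi-empirical engine)
    flow through the same standardization and aggregation as built-in ones.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such file: {path}")
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if lineno == 1 and parts[0].lower() in ("mutation", "mut"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'mutation ddg', got {line!r}")
            spec = MutationSpec.from_string(parts[0])
            try:
                ddg = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: ΔΔG {parts[1]!r} is not a number") from exc
            key = str(spec)
            if key in out:
                raise ValueError(f"{path}:{lineno}: duplicate mutation {key}")
            out[key] = ddg
    return out
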