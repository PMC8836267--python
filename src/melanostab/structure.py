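"""Hierarchical structure model and PDB I/O.

The data model is deliberately small: atoms, residues, a flat structure with
explicit bonds (PDB ``CONECT`` records), and multi-snapshot trajectories.
Metal ions (the binuclear ZnA/ZnB site) and waters are first-class: they are
kept as HETATM residues and the zincs are additionally exposed with role tags
so that active-site geometry checks can address "the zincs" directly.

Parsing and writing go through :mod:`gemmi`; this module only adds the domain
model, validation, and the conventions the analyses rely on (author residue
numbering kept verbatim, highest-occupancy altloc retained, B-factor column
used to export per-residue scores).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

WATER_NAMES = {"HOH", "WAT", "H2O"}

#: Maximum atom serial representable in the fixed-width PDB serial field.
MAX_PDB_SERIAL = 99999


class PDBParseError(ValueError):
    """Raised for unparseable or empty PDB input."""


class SerialOverflowError(ValueError):
    """Raised when a structure cannot be serialized in PDB fixed-width fields."""


@dataclass
class Atom:
    """A single atom: PDB-convention name, element symbol, coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    serial: int
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.serial < 1:
            raise ValueError(f"atom {self.name}: serial must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    """A residue addressed by author numbering (chain, number, insertion code)."""

    chain: str
    number: int
    name: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    @property
    def is_amino(self) -> bool:
        return self.name in STANDARD_AA

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain}{self.number}{self.icode} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms()], dtype=float)

    def copy(self) -> "Residue":
        return Residue(self.chain, self.number, self.name, self.icode,
                       [a.copy() for a in self.atoms])

    def label(self) -> str:
        one = THREE_TO_ONE.get(self.name, "X")
        return f"{one}{self.number}"


@dataclass
class Structure:
    """An ordered collection of residues plus explicit CONECT bonds.

    ``bonds`` holds unordered atom-serial pairs as sorted tuples.  Zinc HETATMs
    are tagged with roles ZnA, ZnB, ... in serial order and are reachable via
    :attr:`metals`.
    """

    residues: list[Residue] = field(default_factory=list)
    bonds: set[tuple[int, int]] = field(default_factory=set)
    name: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms()]
        if len(serials) != len(set(serials)):
            raise ValueError("atom serials must be unique within a structure")
        known = set(serials)
        for a, b in self.bonds:
            if a not in known or b not in known:
                raise ValueError(f"bond ({a},{b}) references a nonexistent atom serial")
        ids = [r.id for r in self.residues]
        if len(ids) != len(set(ids)):
            raise ValueError("(chain, number, icode) must be unique among residues")

    # -- iteration and lookup ------------------------------------------------

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def amino_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_amino]

    @property
    def waters(self) -> list[Residue]:
        return [r for r in self.residues if r.is_water]

    @property
    def metals(self) -> dict[str, Atom]:
        """Zinc ions with role tags ZnA, ZnB, ... in atom-serial order."""
        zincs = sorted(
            (a for r in self.residues for a in r.atoms if a.element.upper() == "ZN"),
            key=lambda a: a.serial,
        )
        return {f"Zn{chr(ord('A') + i)}": a for i, a in enumerate(zincs)}

    def get_residue(self, number: int, chain: str | None = None,
                    icode: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.icode == icode and (chain is None or r.chain == chain):
                return r
        where = f"{chain or '*'}/{number}{icode}"
        raise KeyError(f"no residue {where} in structure")

    def atom_by_serial(self, serial: int) -> Atom:
        for a in self.atoms():
            if a.serial == serial:
                return a
        raise KeyError(f"no atom with serial {serial}")

    def bonded_serials(self, serial: int) -> set[int]:
        """Serials bonded to ``serial``; symmetric regardless of record order."""
        out: set[int] = set()
        for a, b in self.bonds:
            if a == serial:
                out.add(b)
            elif b == serial:
                out.add(a)
        return out

    def topology(self) -> tuple[tuple[str, int, str, str], ...]:
        return tuple((r.chain, r.number, r.icode, r.name) for r in self.residues)

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues], set(self.bonds), self.name)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape does not match atom count")
        for a, row in zip(self.atoms(), xyz):
            a.coords = row.copy()


@dataclass
class Trajectory:
    """Ordered snapshots sharing one residue topology, with times in ns."""

    snapshots: list[Structure]
    times: list[float]

    def __post_init__(self) -> None:
        if len(self.snapshots) != len(self.times):
            raise ValueError("snapshots and times must have equal length")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.snapshots:
            topo = self.snapshots[0].topology()
            for i, s in enumerate(self.snapshots[1:], start=1):
                if s.topology() != topo:
                    raise ValueError(f"snapshot {i} has a different residue topology")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.snapshots)


# ---------------------------------------------------------------------------
# reading

def _validate_pdb_lines(path: Path) -> None:
    """Cheap per-line validation so parse errors can name the offending line."""
    n_coord_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            n_coord_records += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}: malformed {rec} record at line {lineno} (truncated)")
            try:
                int(line[6:11])
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(
                    f"{path}: malformed {rec} record at line {lineno}: {exc}"
                ) from exc
    if n_coord_records == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")


def _residues_from_gemmi_model(model: gemmi.Model) -> list[Residue]:
    residues: list[Residue] = []
    for chain in model:
        for gres in chain:
            # altloc policy: one conformer per atom name, highest occupancy wins
            best: dict[str, gemmi.Atom] = {}
            had_altloc = False
            for ga in gres:
                if ga.altloc not in ("", "\x00"):
                    had_altloc = True
                prev = best.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    best[ga.name] = ga
            if had_altloc:
                logger.warning(
                    "residue %s%d%s: alternate locations present; keeping the "
                    "highest-occupancy conformer per atom",
                    chain.name, gres.seqid.num, gres.seqid.icode.strip(),
                )
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name.upper(),
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    serial=ga.serial,
                    bfactor=ga.b_iso,
                    occupancy=ga.occ,
                )
                for ga in sorted(best.values(), key=lambda a: a.serial)
            ]
            residues.append(
                Residue(
                    chain=chain.name,
                    number=gres.seqid.num,
                    name=gres.name,
                    icode=gres.seqid.icode.strip(),
                    atoms=atoms,
                )
            )
    return residues


def _bonds_from_conect(st: gemmi.Structure) -> set[tuple[int, int]]:
    bonds: set[tuple[int, int]] = set()
    for serial, partners in st.conect_map.items():
        for p in partners:
            bonds.add((min(serial, p), max(serial, p)))
    return bonds


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    All ATOM/HETATM records are kept (zincs, waters and ligands included) and
    CONECT records become explicit bonds.  Only the first MODEL is read; use
    :func:`read_trajectory` for multi-model files.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such file: {path}")
    _validate_pdb_lines(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    residues = _residues_from_gemmi_model(st[0])
    known = {a.serial for r in residues for a in r.atoms}
    bonds = {b for b in _bonds_from_conect(st) if b[0] in known and b[1] in known}
    return Structure(residues=residues, bonds=bonds, name=path.stem)


def read_trajectory(path: str | Path, dt: float = 0.1,
                    times: Sequence[float] | None = None) -> Trajectory:
    """Read a multi-MODEL PDB as a trajectory (default snapshot stride 0.1 ns)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such file: {path}")
    _validate_pdb_lines(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    bonds_all = _bonds_from_conect(st)
    snaps = []
    for model in st:
        residues = _residues_from_gemmi_model(model)
        known = {a.serial for r in residues for a in r.atoms}
        bonds = {b for b in bonds_all if b[0] in known and b[1] in known}
        snaps.append(Structure(residues=residues, bonds=bonds, name=path.stem))
    if times is None:
        times = [dt * i for i in range(len(snaps))]
    return Trajectory(snapshots=snaps, times=list(times))


# ---------------------------------------------------------------------------
# writing

def _to_gemmi(structure: Structure, model_name: str = "1") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.name or "melanostab"
    model = gemmi.Model(model_name)
    chain_map: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        if res.chain not in chain_map:
            chain_map[res.chain] = gemmi.Chain(res.chain)
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
        gres.het_flag = "A" if res.is_amino else "H"
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element.capitalize())
            ga.pos = gemmi.Position(*atom.coords)
            ga.serial = atom.serial
            ga.b_iso = atom.bfactor
            ga.occ = atom.occupancy
            gres.add_atom(ga)
        chain_map[res.chain].add_residue(gres)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    for a, b in sorted(structure.bonds):
        st.add_conect(a, b, 1)
    return st


def _pdb_write_options() -> gemmi.PdbWriteOptions:
    opt = gemmi.PdbWriteOptions()
    opt.conect_records = True
    opt.preserve_serial = True
    opt.cryst1_record = False
    return opt


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write a structure as PDB (fixed-width %8.3f coordinates, CONECT bonds).

    Round-trips through :func:`read_structure` up to the 3-decimal coordinate
    precision of the format.
    """
    path = Path(path)
    max_serial = max((a.serial for a in structure.atoms()), default=0)
    if max_serial > MAX_PDB_SERIAL or structure.n_atoms > MAX_PDB_SERIAL:
        raise SerialOverflowError(
            f"structure has atom serials beyond {MAX_PDB_SERIAL}; "
            "cannot be written in fixed-width PDB format"
        )
    st = _to_gemmi(structure)
    try:
        st.write_pdb(str(path), _pdb_write_options())
    except OSError as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc
    return path


def write_trajectory(trajectory: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a multi-MODEL PDB file."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = "trajectory"
    for i, snap in enumerate(trajectory.snapshots, start=1):
        st.add_model(_to_gemmi(snap, model_name=str(i))[0].clone())
    for a, b in sorted(trajectory.snapshots[0].bonds) if trajectory.snapshots else []:
        st.add_conect(a, b, 1)
    st.write_pdb(str(path), _pdb_write_options())
    return path


# ---------------------------------------------------------------------------
# score export

BFACTOR_SENTINEL = 0.0  # unscored residues: neutral under common viewer ramps


def annotate_bfactor(structure: Structure,
                     scores: Mapping[int | tuple, float]) -> Structure:
    """Return a copy with per-residue scores written into the B-factor column.

    ``scores`` maps residue number (author numbering; applied on every chain
    carrying that number) or ``(chain, number)`` / ``(chain, number, icode)``
    tuples to a score.  Every atom of a scored residue gets the score; all
    other residues get the sentinel 0.00.  A score for a residue absent from
    the structure raises ``KeyError``.
    """
    out = structure.copy()
    resolved: dict[tuple[str, int, str], float] = {}
    for key, value in scores.items():
        if isinstance(key, tuple):
            chain, number = key[0], key[1]
            icode = key[2] if len(key) > 2 else ""
            targets = [r for r in out.residues
                       if r.id == (chain, number, icode)]
        else:
            targets = [r for r in out.residues
                       if r.number == int(key) and r.icode == ""]
        if not targets:
            raise KeyError(f"no residue matching score key {key!r}")
        for r in targets:
            resolved[r.id] = float(value)
    for res in out.residues:
        value = resolved.get(res.id, BFACTOR_SENTINEL)
        for atom in res.atoms:
            atom.bfactor = value
    return out
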