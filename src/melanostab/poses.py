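"""Docking-pose validation, clustering, fingerprints and Kd conversion.

A *pose* is one docked placement of the ligand in the receptor frame, with an
associated binding energy stored positive-favorable (the docking convention
in which larger energies mean tighter binding).  Poses are assumed already
superposed on the receptor, so pose–pose heavy-atom RMSD needs no fitting; a
Kabsch superposition utility is provided separately for structure comparison.

Validity against a binuclear zinc site requires (a) at least one flagged
aromatic-ring oxygen strictly closer than the cutoff (default 4.0 Å) to a
zinc and (b) a productive orientation: both ring oxygens closer to the Zn–Zn
midpoint than the ligand centroid is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stability import GAS_CONSTANT_KCAL
from .structure import (
    Atom,
    Residue,
    Structure,
    Trajectory,
    read_trajectory,
    write_trajectory,
)

__all__ = [
    "Pose",
    "ClusteringParams",
    "PoseCluster",
    "ValidityResult",
    "InteractionFingerprint",
    "ZnContactReport",
    "pose_validity",
    "heavy_atom_rmsd",
    "cluster_poses",
    "interaction_fingerprint",
    "kd_from_energy",
    "zn_contact_report",
    "kabsch_superpose",
    "read_poses",
    "write_poses",
]

#: Default geometric criteria (Å / degrees).
MAX_ZN_DISTANCE = 4.0
HBOND_DISTANCE = 3.5
HBOND_MIN_ANGLE = 120.0
HYDROPHOBIC_DISTANCE = 4.0
PIPI_DISTANCE = 5.5
CONTACT_RADIUS = 4.0
ZN_COORDINATION_DISTANCE = 2.5

#: Ring atoms of the aromatic receptor side chains considered for π–π stacking.
RECEPTOR_RING_ATOMS = {
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


@dataclass
class Pose:
    """A ligand coordinate set with its binding energy (positive = favorable)."""

    pose_id: str
    ligand_atoms: list[Atom]
    binding_energy: float
    ring_oxygens: tuple[str, ...] = ()
    ring_atoms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.binding_energy):
            raise ValueError(f"pose {self.pose_id}: binding energy must be finite")

    def atom(self, name: str) -> Atom:
        for a in self.ligand_atoms:
            if a.name == name:
                return a
        raise KeyError(f"pose {self.pose_id} has no ligand atom {name!r}")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.ligand_atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms()], dtype=float)

    def centroid(self) -> np.ndarray:
        return self.heavy_coords().mean(axis=0)

    def translated(self, shift: np.ndarray) -> "Pose":
        atoms = [Atom(a.name, a.element, a.coords + np.asarray(shift, float),
                      a.serial, a.bfactor, a.occupancy) for a in self.ligand_atoms]
        return Pose(self.pose_id, atoms, self.binding_energy,
                    self.ring_oxygens, self.ring_atoms)


@dataclass
class ClusteringParams:
    """Greedy leader-clustering parameters."""

    rmsd_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be positive")


@dataclass
class PoseCluster:
    representative: Pose
    members: list[Pose]


@dataclass
class ValidityResult:
    """Outcome of the zinc-site validity check, with the failing criterion."""

    valid: bool
    reason: str
    min_oxygen_zn: float

    def __bool__(self) -> bool:
        return self.valid


@dataclass
class InteractionFingerprint:
    """Classified receptor–ligand contacts.

    Atom references use the ``NAME/residue`` style (e.g. ``OD1/N370``);
    hydrogen-bond angles are ``None`` when no hydrogens are present and the
    criterion degrades to distance-only.
    """

    hbonds: list[tuple[str, str, float, float | None]] = field(default_factory=list)
    hydrophobic: list[tuple[str, str, float]] = field(default_factory=list)
    pipi: list[tuple[str, str, float]] = field(default_factory=list)
    contacting_residues: set[str] = field(default_factory=set)


@dataclass
class ZnContactReport:
    """Ring-oxygen-to-zinc distances plus the His coordination shell."""

    oxygen_distances: pd.DataFrame  # columns: oxygen, one per Zn role
    coordinating_his: dict[str, list[str]]

    @property
    def min_distance(self) -> float:
        cols = [c for c in self.oxygen_distances.columns if c != "oxygen"]
        return float(self.oxygen_distances[cols].min().min())


# ---------------------------------------------------------------------------
# validity

def _zinc_positions(receptor: Structure) -> dict[str, np.ndarray]:
    metals = receptor.metals
    if not metals:
        raise ValueError("receptor contains no zinc ions")
    return {role: atom.coords for role, atom in metals.items()}


def pose_validity(pose: Pose, receptor: Structure,
                  max_zn_distance: float = MAX_ZN_DISTANCE) -> ValidityResult:
    """Accept a pose iff a ring oxygen sits strictly below ``max_zn_distance``
    of a zinc *and* the ring oxygens face the metal site.

    The orientation surrogate: both flagged ring oxygens must be closer to the
    Zn–Zn midpoint than the ligand heavy-atom centroid is.
    """
    zincs = _zinc_positions(receptor)
    if not pose.ring_oxygens:
        raise ValueError(f"pose {pose.pose_id}: no aromatic-ring oxygens flagged")
    ox = np.array([pose.atom(n).coords for n in pose.ring_oxygens])
    zn = np.array(list(zincs.values()))
    dists = np.linalg.norm(ox[:, None, :] - zn[None, :, :], axis=-1)
    min_d = float(dists.min())
    if not (min_d < max_zn_distance):
        return ValidityResult(False, "distance", min_d)
    mid = zn.mean(axis=0)
    centroid_d = float(np.linalg.norm(pose.centroid() - mid))
    oxygen_d = np.linalg.norm(ox - mid, axis=1)
    if not np.all(oxygen_d < centroid_d):
        return ValidityResult(False, "orientation", min_d)
    return ValidityResult(True, "ok", min_d)


# ---------------------------------------------------------------------------
# RMSD and clustering

def heavy_atom_rmsd(a: Pose, b: Pose) -> float:
    """Root-mean-square deviation over matched heavy atoms, no refitting."""
    atoms_a, atoms_b = a.heavy_atoms(), b.heavy_atoms()
    if [x.name for x in atoms_a] != [x.name for x in atoms_b]:
        raise ValueError(f"poses {a.pose_id} and {b.pose_id} have mismatched heavy atoms")
    xa = np.array([x.coords for x in atoms_a])
    xb = np.array([x.coords for x in atoms_b])
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def cluster_poses(poses: Sequence[Pose],
                  params: ClusteringParams | None = None) -> list[PoseCluster]:
    """Greedy leader clustering on the energy-sorted pose list.

    Poses are visited best-energy-first (ties broken by pose_id); a pose joins
    the first cluster whose representative is within the RMSD cutoff,
    otherwise it founds a new cluster.  Representatives end up pairwise at
    least the cutoff apart.
    """
    if not poses:
        raise ValueError("cluster_poses requires at least one pose")
    params = params or ClusteringParams()
    ordered = sorted(poses, key=lambda p: (-p.binding_energy, p.pose_id))
    clusters: list[PoseCluster] = []
    for pose in ordered:
        for cluster in clusters:
            if heavy_atom_rmsd(pose, cluster.representative) < params.rmsd_cutoff:
                cluster.members.append(pose)
                break
        else:
            clusters.append(PoseCluster(representative=pose, members=[pose]))
    return clusters


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal rigid superposition (Kabsch); returns fitted coords and RMSD.

    Utility for structure comparison; pose clustering deliberately does not
    use it because poses share the receptor frame.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets must have identical shape")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted = (mobile - mc) @ rot.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return fitted, rmsd


# ---------------------------------------------------------------------------
# interaction fingerprint

def _atom_ref(residue: Residue, atom: Atom) -> str:
    return f"{atom.name}/{residue.label()}"


def _is_apolar_carbon(atom: Atom, peers: Sequence[Atom]) -> bool:
    """Carbon not doubly bonded to oxygen (no O within 1.35 Å in its residue)."""
    if atom.element.upper() != "C":
        return False
    for other in peers:
        if other.element.upper() == "O" and \
                np.linalg.norm(atom.coords - other.coords) <= 1.35:
            return False
    return True


def _hydrogens_on(atom: Atom, peers: Sequence[Atom]) -> list[Atom]:
    return [h for h in peers
            if h.is_hydrogen and np.linalg.norm(h.coords - atom.coords) <= 1.25]


def _donor_angle(donor: Atom, hydrogen: Atom, acceptor: Atom) -> float:
    v1 = donor.coords - hydrogen.coords
    v2 = acceptor.coords - hydrogen.coords
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def interaction_fingerprint(pose: Pose, receptor: Structure,
                            hbond_distance: float = HBOND_DISTANCE,
                            hbond_min_angle: float = HBOND_MIN_ANGLE,
                            hydrophobic_distance: float = HYDROPHOBIC_DISTANCE,
                            pipi_distance: float = PIPI_DISTANCE,
                            contact_radius: float = CONTACT_RADIUS) -> InteractionFingerprint:
    """Classify receptor–ligand contacts by conventional geometric criteria.

    Hydrogen bonds: N/O donor–acceptor pairs within 3.5 Å; when hydrogens
    exist on either partner the best D–H···A angle must reach 120°, otherwise
    the check is distance-only.  Hydrophobic contacts: apolar carbon pairs
    within 4.0 Å.  π–π: aromatic side-chain ring centroid within 5.5 Å of the
    ligand ring centroid.
    """
    fp = InteractionFingerprint()
    ligand_atoms = pose.ligand_atoms
    ligand_heavy = pose.heavy_atoms()

    lig_ring_centroid = None
    if pose.ring_atoms:
        lig_ring_centroid = np.array(
            [pose.atom(n).coords for n in pose.ring_atoms]).mean(axis=0)

    for residue in receptor.residues:
        if residue.is_water or not residue.is_amino:
            continue
        res_heavy = residue.heavy_atoms()
        if not res_heavy:
            continue
        # generic contact check first; skip distant residues early
        rc = np.array([a.coords for a in res_heavy])
        lc = np.array([a.coords for a in ligand_heavy])
        pair_d = np.linalg.norm(rc[:, None, :] - lc[None, :, :], axis=-1)
        if pair_d.min() <= contact_radius:
            fp.contacting_residues.add(residue.label())
        if pair_d.min() > max(hbond_distance, hydrophobic_distance, pipi_distance) + 3.0:
            continue

        for ra in res_heavy:
            for la in ligand_heavy:
                d = float(np.linalg.norm(ra.coords - la.coords))
                if ra.element.upper() in ("N", "O") and la.element.upper() in ("N", "O") \
                        and d <= hbond_distance:
                    angle = None
                    hydrogens = [(ra, h, la) for h in _hydrogens_on(ra, residue.atoms)]
                    hydrogens += [(la, h, ra) for h in _hydrogens_on(la, ligand_atoms)]
                    if hydrogens:
                        angle = max(_donor_angle(dn, h, ac) for dn, h, ac in hydrogens)
                        if angle < hbond_min_angle:
                            continue
                    fp.hbonds.append((_atom_ref(residue, ra), la.name, d, angle))
                if d <= hydrophobic_distance \
                        and _is_apolar_carbon(ra, residue.atoms) \
                        and _is_apolar_carbon(la, ligand_atoms):
                    fp.hydrophobic.append((_atom_ref(residue, ra), la.name, d))

        ring_names = RECEPTOR_RING_ATOMS.get(residue.name)
        if ring_names and lig_ring_centroid is not None \
                and all(residue.has_atom(n) for n in ring_names):
            centroid = np.array([residue.atom(n).coords for n in ring_names]).mean(axis=0)
            d = float(np.linalg.norm(centroid - lig_ring_centroid))
            if d <= pipi_distance:
                fp.pipi.append((residue.label(), "ring", d))
    return fp


# ---------------------------------------------------------------------------
# energies and the zinc contact shell

def kd_from_energy(binding_energy: float, temperature: float = 298.15) -> float:
    """Dissociation constant in molar from a positive-favorable binding energy.

    Kd = exp(-E/RT) × 1 M at standard state; strictly decreasing in E.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    rt = GAS_CONSTANT_KCAL * temperature
    return float(math.exp(-binding_energy / rt))


def zn_contact_report(pose: Pose, receptor: Structure,
                      coordination_distance: float = ZN_COORDINATION_DISTANCE) -> ZnContactReport:
    """Ring-oxygen distances to each zinc plus the His NE2 coordination shell."""
    zincs = _zinc_positions(receptor)
    rows = []
    for name in pose.ring_oxygens:
        pos = pose.atom(name).coords
        row: dict[str, object] = {"oxygen": name}
        for role, zn in zincs.items():
            row[role] = round(float(np.linalg.norm(pos - zn)), 3)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["oxygen", *zincs.keys()])
    shell: dict[str, list[str]] = {}
    for role, zn in zincs.items():
        his = [r.label() for r in receptor.residues
               if r.name == "HIS" and r.has_atom("NE2")
               and np.linalg.norm(r.atom("NE2").coords - zn) <= coordination_distance]
        shell[role] = sorted(his, key=lambda s: int(s[1:]))
    return ZnContactReport(oxygen_distances=frame, coordinating_his=shell)


# ---------------------------------------------------------------------------
# I/O: multi-model PDB + energy sidecar

def read_poses(pdb_path: str | Path, energies_path: str | Path,
               ring_oxygens: Sequence[str] = ("O5", "O6"),
               ring_atoms: Sequence[str] = ()) -> list[Pose]:
    """Read poses from a multi-MODEL PDB plus a (pose_id, binding_energy) TSV.

    Model ``i`` of the PDB pairs with row ``i`` of the sidecar table.
    """
    table = pd.read_csv(energies_path, sep="\t")
    if not {"pose_id", "binding_energy"} <= set(table.columns):
        raise ValueError("energies file must have pose_id and binding_energy columns")
    traj = read_trajectory(pdb_path)
    if len(traj) != len(table):
        raise ValueError(
            f"pose count mismatch: {len(traj)} models vs {len(table)} energy rows")
    poses = []
    for snap, (_, row) in zip(traj, table.iterrows()):
        atoms = [a.copy() for r in snap.residues for a in r.atoms]
        poses.append(Pose(str(row["pose_id"]), atoms, float(row["binding_energy"]),
                          tuple(ring_oxygens), tuple(ring_atoms)))
    return poses


def write_poses(poses: Sequence[Pose], pdb_path: str | Path,
                energies_path: str | Path, ligand_name: str = "LIG",
                ligand_number: int = 900) -> None:
    """Write poses as a multi-MODEL PDB and a binding-energy sidecar TSV."""
    snapshots = []
    for pose in poses:
        res = Residue("L", ligand_number, ligand_name,
                      atoms=[a.copy() for a in pose.ligand_atoms])
        snapshots.append(Structure([res], name=pose.pose_id))
    traj = Trajectory(snapshots=snapshots, times=[float(i) for i in range(len(poses))])
    write_trajectory(traj, pdb_path)
    pd.DataFrame(
        {"pose_id": [p.pose_id for p in poses],
         "binding_energy": [p.binding_energy for p in poses]}
    ).to_csv(energies_path, sep="\t", index=False)
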