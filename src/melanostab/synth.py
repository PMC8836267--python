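"""Synthetic structure generators.

Every analysis stage in this package can be exercised without downloading any
real coordinates.  The generators here produce miniature structures carrying
exactly the geometric features the analyses consume:

* Cys mini-domains with disulfide pairs placed at covalent S–S geometry
  (2.05 Å) and all unpaired SG atoms kept well apart (≥ 6 Å),
* a binuclear zinc site — two Zn ions 3.3 Å apart with a bridging water and
  six histidines whose NE2 atoms coordinate the metals at 2.0–2.2 Å, wired up
  with explicit CONECT bonds,
* catechol-like ligand poses placed at a controlled ring-oxygen-to-zinc
  distance, oriented toward or away from the metal site,
* Gaussian-jittered pseudo-trajectories standing in for MD snapshot series.

Backbones are laid on a coarse helical lattice; only the SG / NE2 / metal /
ligand-oxygen geometry is guaranteed, not stereochemical realism — the
downstream operations consume distances, not backbone energetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .poses import Pose
from .mutation import MutationSpec
from .structure import (
    Atom,
    ONE_TO_THREE,
    Residue,
    Structure,
    Trajectory,
)

__all__ = [
    "FixtureSpec",
    "ZincSiteParams",
    "LigandTemplate",
    "dopachrome_like_template",
    "make_cys_fixture",
    "make_zinc_site_fixture",
    "place_ligand_pose",
    "jitter_trajectory",
    "mutate_residue",
]

#: Covalent disulfide S–S bond length, Å.
SS_BOND_LENGTH = 2.05
#: Minimum separation imposed between SG atoms that are not bridge partners, Å.
SG_CLEARANCE = 6.0

# Coarse helical lattice: radius / twist per residue / rise per residue.
_LATTICE_RADIUS = 10.0
_LATTICE_TWIST = math.radians(40.0)
_LATTICE_RISE = 2.0

_BACKBONE = ("N", "CA", "C", "O")


class FixtureSpecError(ValueError):
    """Raised for inconsistent fixture specifications."""


class FixtureGeometryError(RuntimeError):
    """Raised when a generated fixture violates its own geometric guarantees."""


class MutationMismatchError(ValueError):
    """Raised when the wild-type letter of a mutation does not match the structure."""


@dataclass
class ZincSiteParams:
    """Geometry of the synthetic binuclear zinc site.

    Two zincs separated by ``zn_separation`` share a bridging water midway;
    each is coordinated by three histidine NE2 atoms at ``ne2_distance``.
    """

    zn_separation: float = 3.3
    n_his: int = 6
    ne2_distance: float = 2.1
    his_numbers: tuple[int, ...] = (211, 215, 311, 369, 373, 377)
    chain: str = "A"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    water_number: int = 600
    zn_numbers: tuple[int, int] = (501, 502)
    start_serial: int = 1

    def validate(self) -> None:
        if self.n_his != 6:
            raise FixtureSpecError("a binuclear zinc site requires exactly 6 histidines")
        if len(self.his_numbers) != 6 or len(set(self.his_numbers)) != 6:
            raise FixtureSpecError("his_numbers must be 6 distinct residue numbers")
        if not (2.0 <= self.ne2_distance <= 2.2):
            raise FixtureSpecError("ne2_distance must lie in the 2.0-2.2 Å coordination range")
        if not (2.5 <= self.zn_separation <= 5.0):
            raise FixtureSpecError("zn_separation outside the plausible binuclear range")


@dataclass
class FixtureSpec:
    """Specification of a Cys mini-domain fixture."""

    n_residues: int
    sequence: str = "auto"
    disulfide_pairs: tuple[tuple[int, int], ...] = ()
    zinc_site: ZincSiteParams | None = None
    seed: int = 0

    def resolved_sequence(self) -> str:
        if self.sequence == "auto":
            seq = ["A"] * self.n_residues
            for pair in self.disulfide_pairs:
                for pos in pair:
                    if not 1 <= pos <= self.n_residues:
                        raise FixtureSpecError(
                            f"disulfide position {pos} outside 1..{self.n_residues}"
                        )
                    seq[pos - 1] = "C"
            return "".join(seq)
        if len(self.sequence) != self.n_residues:
            raise FixtureSpecError("sequence length does not match n_residues")
        return self.sequence

    def validate(self) -> str:
        if self.n_residues < 1:
            raise FixtureSpecError("n_residues must be positive")
        seq = self.resolved_sequence()
        seen: set[int] = set()
        for a, b in self.disulfide_pairs:
            if a == b:
                raise FixtureSpecError(f"disulfide pair ({a},{b}) pairs a residue with itself")
            for pos in (a, b):
                if not 1 <= pos <= self.n_residues:
                    raise FixtureSpecError(f"disulfide position {pos} outside 1..{self.n_residues}")
                if seq[pos - 1] != "C":
                    raise FixtureSpecError(
                        f"disulfide pair references position {pos}, which is {seq[pos - 1]}, not Cys"
                    )
                if pos in seen:
                    raise FixtureSpecError(f"position {pos} appears in more than one disulfide pair")
                seen.add(pos)
        return seq


# ---------------------------------------------------------------------------
# Cys mini-domain

def _lattice_frame(index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """CA position plus (radial, tangent, axial) unit vectors for residue index."""
    phi = index * _LATTICE_TWIST
    radial = np.array([math.cos(phi), math.sin(phi), 0.0])
    tangent = np.array([-math.sin(phi), math.cos(phi), 0.0])
    axial = np.array([0.0, 0.0, 1.0])
    ca = _LATTICE_RADIUS * radial + np.array([0.0, 0.0, index * _LATTICE_RISE])
    return ca, radial, tangent, axial


def make_cys_fixture(spec: FixtureSpec) -> Structure:
    """Build a mini-domain realizing the requested disulfide topology.

    Paired SG atoms sit exactly 2.05 Å apart on the axis between their CA
    positions; every other SG–SG distance is at least 6 Å, so a geometric
    bridge detector recovers exactly the requested pairing.
    """
    seq = spec.validate()
    serial = 1
    residues: list[Residue] = []
    paired = {p for pair in spec.disulfide_pairs for p in pair}

    sg_override: dict[int, np.ndarray] = {}
    for a, b in spec.disulfide_pairs:
        ca_a, _, _, _ = _lattice_frame(a - 1)
        ca_b, _, _, _ = _lattice_frame(b - 1)
        mid = (ca_a + ca_b) / 2.0
        axis = ca_b - ca_a
        axis = axis / np.linalg.norm(axis)
        sg_override[a] = mid - axis * (SS_BOND_LENGTH / 2.0)
        sg_override[b] = mid + axis * (SS_BOND_LENGTH / 2.0)

    for i, one in enumerate(seq):
        number = i + 1
        ca, radial, tangent, axial = _lattice_frame(i)
        name = ONE_TO_THREE[one]
        atoms = [
            Atom("N", "N", ca - 1.45 * tangent, serial),
            Atom("CA", "C", ca, serial + 1),
            Atom("C", "C", ca + 1.45 * tangent, serial + 2),
            Atom("O", "O", ca + 1.45 * tangent + 1.23 * axial, serial + 3),
        ]
        serial += 4
        if one != "G":
            atoms.append(Atom("CB", "C", ca + 1.53 * radial, serial))
            serial += 1
        if one == "C":
            if number in sg_override:
                sg = sg_override[number]
            else:
                sg = ca + 3.0 * radial
            atoms.append(Atom("SG", "S", sg, serial))
            serial += 1
        residues.append(Residue("A", number, name, atoms=atoms))

    structure = Structure(residues=residues, name="cys_fixture")

    # verify the advertised geometric guarantees
    sg_pos = {r.number: r.atom("SG").coords for r in residues if r.has_atom("SG")}
    partner = {}
    for a, b in spec.disulfide_pairs:
        partner[a], partner[b] = b, a
        d = float(np.linalg.norm(sg_pos[a] - sg_pos[b]))
        if abs(d - SS_BOND_LENGTH) > 1e-3:
            raise FixtureGeometryError(f"pair ({a},{b}): SG-SG distance {d:.3f} != {SS_BOND_LENGTH}")
    nums = sorted(sg_pos)
    for i, a in enumerate(nums):
        for b in nums[i + 1:]:
            if partner.get(a) == b:
                continue
            d = float(np.linalg.norm(sg_pos[a] - sg_pos[b]))
            if d < SG_CLEARANCE:
                raise FixtureGeometryError(
                    f"non-partner SG atoms {a} and {b} are only {d:.2f} Å apart; "
                    "requested pairing cannot be realized on the lattice"
                )

    if spec.zinc_site is not None:
        site_params = spec.zinc_site
        used = {r.number for r in residues}
        if used & set(site_params.his_numbers) or used & set(site_params.zn_numbers):
            raise FixtureSpecError("zinc-site residue numbers collide with the mini-domain")
        shifted = ZincSiteParams(**{**site_params.__dict__,
                                    "center": (0.0, 0.0, -25.0),
                                    "start_serial": serial})
        site = make_zinc_site_fixture(shifted)
        structure = Structure(residues + site.residues, set(site.bonds), structure.name)
    return structure


# ---------------------------------------------------------------------------
# binuclear zinc site

_HIS_LOCAL = {
    # imidazole ring as a regular pentagon (side ~1.37 Å), NE2 at the origin,
    # ring and stub extending along +x, all in the xy-plane
    "NE2": (0.000, 0.000, 0.000),
    "CE1": (0.806, 1.109, 0.000),
    "CD2": (0.806, -1.109, 0.000),
    "ND1": (2.109, 0.685, 0.000),
    "CG": (2.109, -0.685, 0.000),
    "CB": (3.309, -1.585, 0.000),
    "CA": (4.609, -0.785, 0.000),
    "N": (4.609, 0.665, 0.000),
    "C": (5.809, -1.585, 0.000),
    "O": (6.309, -2.685, 0.000),
}
_HIS_ELEMENTS = {"NE2": "N", "ND1": "N", "N": "N", "O": "O"}


def _rotation_from_x(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix sending +x to ``direction`` (unit)."""
    x = np.array([1.0, 0.0, 0.0])
    d = direction / np.linalg.norm(direction)
    v = np.cross(x, d)
    c = float(np.dot(x, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def make_zinc_site_fixture(params: ZincSiteParams | None = None) -> Structure:
    """Build the binuclear Zn site: ZnA, ZnB, bridging water, six His.

    NE2 atoms coordinate their assigned zinc at ``ne2_distance`` (three per
    Zn) and each Zn–NE2 pair carries an explicit CONECT bond.  The tripods
    point into the -z half-space, leaving +z open as the substrate approach
    direction.
    """
    params = params or ZincSiteParams()
    params.validate()
    center = np.asarray(params.center, dtype=float)
    half = params.zn_separation / 2.0
    zn_a = center + np.array([-half, 0.0, 0.0])
    zn_b = center + np.array([half, 0.0, 0.0])

    serial = params.start_serial
    residues: list[Residue] = []
    bonds: set[tuple[int, int]] = set()

    # tripod directions: x-component pushes away from the partner zinc,
    # azimuths keep every NE2 at z <= 0
    azimuths = [math.radians(a) for a in (210.0, 270.0, 330.0)]

    def tripod(sign: float) -> list[np.ndarray]:
        dirs = []
        for az in azimuths:
            d = np.array([0.70 * sign, 0.714 * math.cos(az), 0.714 * math.sin(az)])
            dirs.append(d / np.linalg.norm(d))
        return dirs

    his_iter = iter(params.his_numbers)
    zn_serials: list[int] = []
    ne2_serials: dict[int, list[int]] = {}

    his_defs: list[tuple[int, np.ndarray, np.ndarray]] = []
    for zn_pos, sign in ((zn_a, -1.0), (zn_b, 1.0)):
        for d in tripod(sign):
            his_defs.append((next(his_iter), zn_pos + params.ne2_distance * d, d))

    for idx, (number, ne2_pos, outward) in enumerate(his_defs):
        rot = _rotation_from_x(outward)
        atoms = []
        ne2_serial = None
        for atom_name in ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"):
            local = np.array(_HIS_LOCAL[atom_name])
            pos = ne2_pos + rot @ local
            atoms.append(Atom(atom_name, _HIS_ELEMENTS.get(atom_name, "C"), pos, serial))
            if atom_name == "NE2":
                ne2_serial = serial
            serial += 1
        residues.append(Residue(params.chain, number, "HIS", atoms=atoms))
        ne2_serials.setdefault(idx // 3, []).append(ne2_serial)

    for role_idx, zn_pos in enumerate((zn_a, zn_b)):
        zn_atom = Atom("ZN", "ZN", zn_pos, serial)
        residues.append(Residue(params.chain, params.zn_numbers[role_idx], "ZN",
                                atoms=[zn_atom]))
        zn_serials.append(serial)
        serial += 1
    residues.append(Residue(params.chain, params.water_number, "HOH",
                            atoms=[Atom("O", "O", center.copy(), serial)]))
    serial += 1

    for role_idx, zn_serial in enumerate(zn_serials):
        for ne2 in ne2_serials[role_idx]:
            bonds.add((min(zn_serial, ne2), max(zn_serial, ne2)))

    return Structure(residues=residues, bonds=bonds, name="zinc_site")


# ---------------------------------------------------------------------------
# ligand template and pose placement

@dataclass
class LigandTemplate:
    """A planar catechol-like bicyclic ligand (dopachrome-like).

    An aromatic six-ring fused to a five-ring, two phenolic oxygens on the
    six-ring, and a carboxylate on the five-ring.  Only the ring-oxygen
    geometry matters to the validity checks downstream.
    """

    atoms: tuple[tuple[str, str, tuple[float, float, float]], ...]
    ring_atoms: tuple[str, ...]
    ring_oxygens: tuple[str, ...]

    def __post_init__(self) -> None:
        names = [a[0] for a in self.atoms]
        if len(self.ring_oxygens) != 2:
            raise ValueError("exactly two aromatic-ring oxygens must be flagged")
        for n in self.ring_oxygens + self.ring_atoms:
            if n not in names:
                raise ValueError(f"flagged atom {n!r} not among template atoms")
        ring = np.array([a[2] for a in self.atoms if a[0] in self.ring_atoms])
        centered = ring - ring.mean(axis=0)
        normal = np.linalg.svd(centered)[2][-1]
        if np.abs(centered @ normal).max() > 0.1:
            raise ValueError("ring atoms deviate from a common plane by more than 0.1 Å")

    def coords(self) -> np.ndarray:
        return np.array([a[2] for a in self.atoms], dtype=float)


def dopachrome_like_template() -> LigandTemplate:
    """Idealized planar bicyclic template with 1.39 Å aromatic bonds."""
    atoms = (
        ("C3A", "C", (1.2037, 0.6950, 0.0)),
        ("C4", "C", (0.0000, 1.3900, 0.0)),
        ("C5", "C", (-1.2037, 0.6950, 0.0)),
        ("C6", "C", (-1.2037, -0.6950, 0.0)),
        ("C7", "C", (0.0000, -1.3900, 0.0)),
        ("C7A", "C", (1.2037, -0.6950, 0.0)),
        ("C3", "C", (2.5256, 1.1242, 0.0)),
        ("C2", "C", (3.3423, 0.0000, 0.0)),
        ("N1", "N", (2.5256, -1.1242, 0.0)),
        ("O5", "O", (-2.3815, 1.3751, 0.0)),
        ("O6", "O", (-2.3815, -1.3751, 0.0)),
        ("C9", "C", (4.8423, 0.0000, 0.0)),
        ("O91", "O", (5.4673, 1.0825, 0.0)),
        ("O92", "O", (5.4673, -1.0825, 0.0)),
    )
    return LigandTemplate(
        atoms=atoms,
        ring_atoms=("C3A", "C4", "C5", "C6", "C7", "C7A"),
        ring_oxygens=("O5", "O6"),
    )


class StericError(ValueError):
    """Raised when a requested ligand placement would clash with the metals."""


def _site_frame(site: Structure) -> tuple[np.ndarray, list[np.ndarray], np.ndarray, np.ndarray]:
    metals = site.metals
    if not metals:
        raise ValueError("site structure contains no zinc ions")
    zn_pos = [metals[k].coords for k in sorted(metals)]
    mid = np.mean(zn_pos, axis=0)
    if len(zn_pos) >= 2:
        x_axis = zn_pos[1] - zn_pos[0]
        x_axis = x_axis / np.linalg.norm(x_axis)
    else:
        x_axis = np.array([1.0, 0.0, 0.0])
    up = np.array([0.0, 0.0, 1.0])
    z_axis = up - np.dot(up, x_axis) * x_axis
    if np.linalg.norm(z_axis) < 1e-8:
        z_axis = np.array([0.0, 1.0, 0.0]) - x_axis[1] * x_axis
    z_axis = z_axis / np.linalg.norm(z_axis)
    return mid, zn_pos, x_axis, z_axis


def place_ligand_pose(
    site: Structure,
    template: LigandTemplate | None = None,
    oxygen_zn_distance: float = 2.4,
    orientation: str = "toward",
    pose_id: str = "pose",
    binding_energy: float = 6.0,
) -> Pose:
    """Place the ligand so its nearest ring oxygen sits at a set Zn distance.

    ``orientation="toward"`` points the ring oxygens at the Zn–Zn midpoint
    (the ligand body behind them, as a productive substrate approach);
    ``"away"`` flips the ligand so the oxygens face away from the midpoint.
    The requested oxygen–zinc distance is honored in both modes (±0.05 Å over
    1.8–8 Å); orientation is what downstream validity checking rejects.
    """
    if oxygen_zn_distance < 1.5:
        raise StericError(
            f"requested oxygen-Zn distance {oxygen_zn_distance} Å is below the 1.5 Å steric floor"
        )
    if orientation not in ("toward", "away"):
        raise ValueError("orientation must be 'toward' or 'away'")
    template = template or dopachrome_like_template()

    mid, zn_pos, x_axis, z_axis = _site_frame(site)
    y_axis = np.cross(z_axis, x_axis)

    local = template.coords()
    names = [a[0] for a in template.atoms]
    ox_idx = [names.index(n) for n in template.ring_oxygens]
    o_mid_local = local[ox_idx].mean(axis=0)
    centroid_local = local.mean(axis=0)
    body = centroid_local - o_mid_local
    body_len = float(np.linalg.norm(body))
    body_dir = body / body_len
    o_axis = local[ox_idx[1]] - local[ox_idx[0]]
    o_axis = o_axis - np.dot(o_axis, body_dir) * body_dir
    o_axis = o_axis / np.linalg.norm(o_axis)
    third = np.cross(body_dir, o_axis)

    # ligand frame -> site frame: oxygen pair along the Zn-Zn axis, body along
    # +z (toward: body above the oxygens) or -z (away: oxygens above the body)
    body_target = z_axis if orientation == "toward" else -z_axis
    basis_local = np.column_stack([body_dir, o_axis, third])
    basis_site = np.column_stack([body_target, x_axis, np.cross(body_target, x_axis)])
    rot = basis_site @ basis_local.T

    def oxygens_at(t: float) -> np.ndarray:
        shift = mid + t * z_axis - rot @ o_mid_local
        return (rot @ local[ox_idx].T).T + shift

    def min_dist(t: float) -> float:
        ox = oxygens_at(t)
        return min(float(np.linalg.norm(o - z)) for o in ox for z in zn_pos)

    lo, hi = 0.0, 100.0
    if min_dist(lo) > oxygen_zn_distance:
        raise StericError(
            f"cannot reach oxygen-Zn distance {oxygen_zn_distance} Å: floor is {min_dist(lo):.2f} Å"
        )
    for _ in range(80):
        t = 0.5 * (lo + hi)
        if min_dist(t) < oxygen_zn_distance:
            lo = t
        else:
            hi = t
    # land on the >= side so a pose requested exactly at a cutoff is excluded
    # by the strict < comparison downstream
    t = hi

    shift = mid + t * z_axis - rot @ o_mid_local
    placed = (rot @ local.T).T + shift
    start_serial = max((a.serial for a in site.atoms()), default=0) + 1
    atoms = [
        Atom(name, elem, placed[i], start_serial + i)
        for i, (name, elem, _) in enumerate(template.atoms)
    ]
    return Pose(
        pose_id=pose_id,
        ligand_atoms=atoms,
        binding_energy=binding_energy,
        ring_oxygens=template.ring_oxygens,
        ring_atoms=template.ring_atoms,
    )


# ---------------------------------------------------------------------------
# pseudo-trajectories and point mutations

def jitter_trajectory(structure: Structure, n: int, sigma: float, seed: int,
                      dt: float = 0.1) -> Trajectory:
    """Gaussian-jittered snapshot series (i.i.d. per-atom displacement, sd sigma).

    Stands in for an MD snapshot series; identical topology throughout, one
    snapshot every ``dt`` ns, bit-identical output for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    base = structure.coords()
    snapshots = []
    for _ in range(n):
        snap = structure.copy()
        snap.set_coords(base + rng.normal(0.0, sigma, size=base.shape))
        snapshots.append(snap)
    times = [dt * (i + 1) for i in range(n)]
    return Trajectory(snapshots=snapshots, times=times)


_SIDE_CHAIN_KEEP = set(_BACKBONE) | {"CB"}


def mutate_residue(structure: Structure, mutation: MutationSpec,
                   chain: str | None = None) -> Structure:
    """Apply a point substitution by renaming and truncating the side chain.

    The residue is renamed to the target; side-chain atoms beyond CB are
    removed (CB as well when mutating to Gly); the backbone and every other
    residue are untouched.  Raises :class:`MutationMismatchError` when the
    wild-type letter does not match the structure.
    """
    out = structure.copy()
    res = out.get_residue(mutation.position, chain=chain)
    expected = ONE_TO_THREE.get(mutation.wt)
    if res.name != expected:
        raise MutationMismatchError(
            f"residue {mutation.position} is {res.name}, not {expected} "
            f"as required by {mutation}"
        )
    res.name = ONE_TO_THREE[mutation.mut]
    keep = set(_BACKBONE) if mutation.mut == "G" else _SIDE_CHAIN_KEEP
    removed = {a.serial for a in res.atoms if a.name not in keep}
    res.atoms = [a for a in res.atoms if a.name in keep]
    out.bonds = {b for b in out.bonds if not (b[0] in removed or b[1] in removed)}
    return out
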