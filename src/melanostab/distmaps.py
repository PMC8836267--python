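"""Residue–residue distance maps and snapshot-to-snapshot comparison.

Distance maps are symmetric matrices of inter-residue distances (CA–CA by
default, or minimum heavy-atom) over the standard amino-acid residues of a
structure.  Because distances are invariant under rigid-body motion, the
entrywise difference of two maps isolates genuine conformational change from
global tumbling — this is the comparison used to ask whether a mutant
trajectory drifts away from its reference conformation.

"No structural fluctuation" is operationalized as a named statistic: the
fraction of residue pairs whose distance changes by more than a threshold
(default 2.0 Å) relative to the reference snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure import Structure, Trajectory

__all__ = [
    "DistanceMap",
    "DistanceDifference",
    "FluctuationSummary",
    "distance_map",
    "map_difference",
    "fluctuation_summary",
]

#: Default |Δd| threshold for calling a residue-pair distance "changed", Å.
DEFAULT_CHANGE_THRESHOLD = 2.0


@dataclass
class DistanceMap:
    """Symmetric residue–residue distance matrix in Å.

    ``residue_ids`` are (chain, number, icode) triples in structure order.
    """

    residue_ids: tuple[tuple[str, int, str], ...]
    matrix: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.residue_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match residue count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.all(np.isfinite(self.matrix)) or self.matrix.min() < -1e-12:
            raise ValueError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.residue_ids)

    def entry(self, number_a: int, number_b: int) -> float:
        idx = {rid[1]: i for i, rid in enumerate(self.residue_ids)}
        return float(self.matrix[idx[number_a], idx[number_b]])

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{c}{n}{i}" for c, n, i in self.residue_ids]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


@dataclass
class DistanceDifference:
    """Entrywise signed difference of two distance maps (antisymmetric in its
    arguments, symmetric as a matrix)."""

    residue_ids: tuple[tuple[str, int, str], ...]
    matrix: np.ndarray
    mode: str

    def max_abs(self) -> float:
        return float(np.abs(self.matrix).max()) if len(self.matrix) else 0.0

    def fraction_exceeding(self, threshold: float) -> float:
        n = len(self.residue_ids)
        if n < 2:
            return 0.0
        iu = np.triu_indices(n, k=1)
        return float(np.mean(np.abs(self.matrix[iu]) > threshold))


@dataclass
class FluctuationSummary:
    """Per-snapshot distance-map deviation from a reference structure."""

    per_snapshot: pd.DataFrame  # columns: time_ns, max_abs_delta, frac_exceeding
    mean_max_abs_delta: float
    mean_frac_exceeding: float
    threshold: float
    mode: str


def distance_map(structure: Structure, mode: str = "CA") -> DistanceMap:
    """Compute the residue–residue distance matrix.

    ``mode="CA"`` uses CA–CA distances (robust to side-chain truncation from
    in-silico substitutions); ``mode="min-heavy"`` uses the minimum distance
    over all heavy-atom pairs of the two residues.
    """
    residues = structure.amino_residues()
    if not residues:
        raise ValueError("structure contains no standard amino-acid residues")
    ids = tuple(r.id for r in residues)
    if mode == "CA":
        coords = []
        for r in residues:
            if not r.has_atom("CA"):
                raise ValueError(f"residue {r.chain}{r.number}{r.icode} has no CA atom")
            coords.append(r.atom("CA").coords)
        matrix = cdist(np.array(coords), np.array(coords))
    elif mode == "min-heavy":
        all_coords = []
        owner = []
        for i, r in enumerate(residues):
            hv = r.heavy_coords()
            if len(hv) == 0:
                raise ValueError(f"residue {r.chain}{r.number}{r.icode} has no heavy atoms")
            all_coords.append(hv)
            owner.extend([i] * len(hv))
        stacked = np.vstack(all_coords)
        owner = np.asarray(owner)
        atom_d = cdist(stacked, stacked)
        n = len(residues)
        matrix = np.full((n, n), np.inf)
        np.minimum.at(matrix, (owner[:, None], owner[None, :]), atom_d)
        np.fill_diagonal(matrix, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'CA' or 'min-heavy'")
    np.fill_diagonal(matrix, 0.0)
    matrix = 0.5 * (matrix + matrix.T)  # exact symmetry against fp jitter
    return DistanceMap(residue_ids=ids, matrix=matrix, mode=mode)


def map_difference(a: DistanceMap, b: DistanceMap) -> DistanceDifference:
    """Entrywise a − b; requires identical residue index and mode."""
    if a.mode != b.mode:
        raise ValueError(f"mode mismatch: {a.mode!r} vs {b.mode!r}")
    if a.residue_ids != b.residue_ids:
        raise ValueError("residue indices differ; maps are not comparable")
    return DistanceDifference(residue_ids=a.residue_ids,
                              matrix=a.matrix - b.matrix, mode=a.mode)


def fluctuation_summary(trajectory: Trajectory, reference: Structure,
                        threshold: float = DEFAULT_CHANGE_THRESHOLD,
                        mode: str = "CA") -> FluctuationSummary:
    """Distance-map deviation of every snapshot from a reference structure.

    For each snapshot: the largest |Δd| over residue pairs and the fraction
    of pairs with |Δd| above ``threshold``; plus trajectory-wide means.
    """
    ref_map = distance_map(reference, mode=mode)
    rows = []
    for time, snap in zip(trajectory.times, trajectory.snapshots):
        snap_map = distance_map(snap, mode=mode)
        diff = map_difference(snap_map, ref_map)
        rows.append({
            "time_ns": time,
            "max_abs_delta": diff.max_abs(),
            "frac_exceeding": diff.fraction_exceeding(threshold),
        })
    frame = pd.DataFrame(rows, columns=["time_ns", "max_abs_delta", "frac_exceeding"])
    return FluctuationSummary(
        per_snapshot=frame,
        mean_max_abs_delta=float(frame["max_abs_delta"].mean()),
        mean_frac_exceeding=float(frame["frac_exceeding"].mean()),
        threshold=threshold,
        mode=mode,
    )
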