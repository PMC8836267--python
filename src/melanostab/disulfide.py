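"""Geometric disulfide-bridge detection and mutation breakage analysis.

A disulfide bridge is detected purely from geometry: two cysteine SG atoms
within a covalent-distance cutoff (default 2.5 Å; the covalent S–S bond is
~2.05 Å).  Candidate pairs are matched greedily by ascending distance so the
result is deterministic and each Cys joins at most one bridge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mutation import MutationSpec
from .structure import Residue, Structure

logger = logging.getLogger(__name__)

#: Default SG-SG detection cutoff, Å.
DEFAULT_SS_CUTOFF = 2.5


@dataclass(frozen=True)
class DisulfideBridge:
    """One bridge, ordered so that res_a < res_b (author numbering)."""

    res_a: int
    res_b: int
    sg_distance: float
    chain_a: str = "A"
    chain_b: str = "A"
    domain_label: str | None = None

    def __post_init__(self) -> None:
        if (self.res_a, self.chain_a) == (self.res_b, self.chain_b):
            raise ValueError("a bridge must join two distinct residues")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.res_a, self.res_b)

    def involves(self, position: int) -> bool:
        return position in (self.res_a, self.res_b)

    def __str__(self) -> str:
        return f"C{self.res_a}-C{self.res_b}"


def detect_disulfides(structure: Structure,
                      cutoff: float = DEFAULT_SS_CUTOFF) -> list[DisulfideBridge]:
    """Find disulfide bridges by greedy nearest-SG matching under ``cutoff``.

    Cysteines lacking an SG atom (e.g. after an in-silico substitution)
    simply cannot match.  Returns bridges sorted by the lower residue number.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cys = [(r, r.atom("SG")) for r in structure.residues
           if r.name == "CYS" and r.has_atom("SG")]
    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i][1].coords - cys[j][1].coords))
            if d <= cutoff:
                candidates.append((d, i, j))
    candidates.sort(key=lambda c: (c[0], cys[c[1]][0].id, cys[c[2]][0].id))

    matched: set[int] = set()
    bridges: list[DisulfideBridge] = []
    for d, i, j in candidates:
        if i in matched or j in matched:
            continue
        matched.update((i, j))
        ra, rb = cys[i][0], cys[j][0]
        if (ra.number, ra.chain) > (rb.number, rb.chain):
            ra, rb = rb, ra
        bridges.append(DisulfideBridge(ra.number, rb.number, d, ra.chain, rb.chain))
    bridges.sort(key=lambda b: (b.res_a, b.res_b))
    return bridges


def broken_bridges(bridges: Iterable[DisulfideBridge],
                   mutation: MutationSpec) -> list[DisulfideBridge]:
    """Bridges eliminated by a substitution (Cys mutated to a non-Cys)."""
    if mutation.wt != "C" or mutation.mut == "C":
        return []
    return [b for b in bridges if b.involves(mutation.position)]


def label_domains(bridges: Iterable[DisulfideBridge],
                  ranges: Mapping[str, tuple[int, int]]) -> list[DisulfideBridge]:
    """Label each bridge by the residue interval containing both members.

    ``ranges`` maps a domain label (e.g. "Cys-rich", "tyrosinase") to an
    inclusive residue interval.  Bridges spanning two labeled intervals, or
    contained in none, are labeled "other".
    """
    items = sorted(ranges.items(), key=lambda kv: kv[1])
    for (la, (a1, a2)), (lb, (b1, b2)) in zip(items, items[1:]):
        if b1 <= a2:
            raise ValueError(f"domain intervals {la!r} and {lb!r} overlap")
    out = []
    for bridge in bridges:
        label_a = next((l for l, (lo, hi) in items if lo <= bridge.res_a <= hi), None)
        label_b = next((l for l, (lo, hi) in items if lo <= bridge.res_b <= hi), None)
        if label_a is not None and label_a == label_b:
            label = label_a
        else:
            if label_a is not None and label_b is not None and label_a != label_b:
                logger.warning("bridge %s spans domains %s and %s; labeling as 'other'",
                               bridge, label_a, label_b)
            label = "other"
        out.append(replace(bridge, domain_label=label))
    return out


def bridges_frame(bridges: Sequence[DisulfideBridge]) -> pd.DataFrame:
    """Bridge list as a table (res_a, res_b, distance, domain)."""
    return pd.DataFrame(
        [
            {
                "res_a": b.res_a,
                "res_b": b.res_b,
                "sg_distance": round(b.sg_distance, 3),
                "domain": b.domain_label or "",
            }
            for b in bridges
        ],
        columns=["res_a", "res_b", "sg_distance", "domain"],
    )
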