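"""Bounded-Lorentz distance restraints for contact-guided folding.

A predicted contact is rewarded, never penalized: the restraint energy is
a constant bonus of -w while the inter-residue distance lies between the
lower and upper bound, and decays to zero through a Lorentzian of half
width ``hw`` outside the bounds.  Because predictions contain false
positives, a violated restraint costs nothing — the term only maximizes
the number of satisfied contacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from .structio import ProteinStructure

__all__ = [
    "RestraintParams",
    "lorentz_energy",
    "write_restraint_file",
    "read_restraint_file",
    "write_rosetta_restraints",
]


@dataclass(frozen=True)
class RestraintParams:
    """Bounds (A), half width (A), bonus magnitude and emitted count."""

    lb: float = 1.5
    ub: float = 8.0
    hw: float = 1.0
    w: float = 1.0
    n_contacts: int | None = None  # None: top L

    def __post_init__(self) -> None:
        if not (self.lb < self.ub and self.hw > 0 and self.w > 0):
            raise ValueError("require lb < ub, hw > 0, w > 0")


def lorentz_energy(d: float, p: RestraintParams = RestraintParams()) -> float:
    """Restraint energy at distance d: -w inside [lb, ub], Lorentzian
    decay to 0 outside; at a violation of one half width the bonus is
    halved.  Always in [-w, 0]."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if p.lb <= d <= p.ub:
        return -p.w
    violation = (d - p.ub) if d > p.ub else (p.lb - d)
    return -p.w / (1.0 + (violation / p.hw) ** 2)


def write_restraint_file(
    ranked: list[tuple[int, int, float]],
    path: str | Path,
    p: RestraintParams = RestraintParams(),
    structure: ProteinStructure | None = None,
    L: int | None = None,
) -> int:
    """Emit the top-ranked contacts as a TSV of bounded-Lorentz restraints.

    Columns: i, j, atom_i, atom_j, lb, ub, hw, w.  The restrained atom is
    CB, or CA for glycine when the sequence is known.  Returns the number
    of restraints written.
    """
    if not ranked:
        raise ValueError("no ranked contacts")
    n = p.n_contacts
    if n is None:
        n = L if L is not None else len(ranked)
    if n > len(ranked):
        warnings.warn(
            f"requested {n} restraints but only {len(ranked)} contacts ranked"
        )
        n = len(ranked)

    def atom_for(res_index: int) -> str:
        if structure is not None and structure.residues[res_index - 1].aa == "G":
            return "CA"
        return "CB"

    lines = ["#i\tj\tatom_i\tatom_j\tlb\tub\thw\tw"]
    for i, j, _score in ranked[:n]:
        lines.append(
            f"{i}\t{j}\t{atom_for(i)}\t{atom_for(j)}\t"
            f"{p.lb:g}\t{p.ub:g}\t{p.hw:g}\t{p.w:g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return n


def read_restraint_file(
    path: str | Path,
) -> list[tuple[int, int, str, str, RestraintParams]]:
    """Parse a restraint TSV back into rows with exact parameters."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        i, j, ai, aj, lb, ub, hw, w = line.split("\t")
        rows.append(
            (int(i), int(j), ai, aj,
             RestraintParams(float(lb), float(ub), float(hw), float(w)))
        )
    return rows


def write_rosetta_restraints(
    ranked: list[tuple[int, int, float]],
    path: str | Path,
    p: RestraintParams = RestraintParams(),
    structure: ProteinStructure | None = None,
    L: int | None = None,
) -> int:
    """Approximate export in Rosetta constraint-file syntax
    (``AtomPair CB i CB j BOUNDED lb ub sd``); the BOUNDED form penalizes
    outside the bounds rather than rewarding inside them, so this is a
    labeled approximation of the bounded-Lorentz term."""
    if not ranked:
        raise ValueError("no ranked contacts")
    n = p.n_contacts or (L if L is not None else len(ranked))
    n = min(n, len(ranked))

    def atom_for(res_index: int) -> str:
        if structure is not None and structure.residues[res_index - 1].aa == "G":
            return "CA"
        return "CB"

    lines = [
        f"AtomPair {atom_for(i)} {i} {atom_for(j)} {j} "
        f"BOUNDED {p.lb:g} {p.ub:g} {p.hw:g}"
        for i, j, _ in ranked[:n]
    ]
    Path(path).write_text("\n".join(lines) + "\n")
    return n
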