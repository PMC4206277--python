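"""Structure, alignment and score-file I/O plus the basic contact relation.

Conventions used throughout the package:

* residues are numbered 1..L in order of appearance, independent of author
  numbering or insertion codes;
* a contact is a pair of residues whose Cb atoms (Ca for glycine) lie
  within 8 A;
* decoy energies arrive in a sidecar two-column TSV, never parsed from
  PDB remarks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1
from scipy.spatial.distance import pdist, squareform

from . import config

__all__ = [
    "ResidueRecord",
    "ProteinStructure",
    "ContactMap",
    "DecoyEnsemble",
    "Msa",
    "EvolutionaryScores",
    "read_structure",
    "write_structure",
    "contact_atom",
    "compute_contact_map",
    "read_msa",
    "read_evolutionary_scores",
    "read_energy_table",
    "select_low_energy",
    "write_rr",
    "read_rr",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ResidueRecord:
    """One residue: chain, serial 1-based index, amino acid and atoms."""

    chain_id: str
    seq_index: int
    aa: str
    atoms: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.aa not in STANDARD_AA and self.aa != "X":
            self.aa = "X"


@dataclass
class ProteinStructure:
    """An ordered chain of residues (a native structure or one decoy)."""

    id: str
    residues: list[ResidueRecord]

    @property
    def L(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def coords(self, atom: str = "CA") -> np.ndarray:
        """(L, 3) array of the named atom; NaN rows where absent."""
        out = np.full((self.L, 3), np.nan)
        for k, res in enumerate(self.residues):
            if atom in res.atoms:
                out[k] = res.atoms[atom]
        return out

    def contact_coords(self) -> np.ndarray:
        """(L, 3) array of per-residue contact atoms (Cb, Ca for Gly)."""
        return np.array([contact_atom(r) for r in self.residues])

    def chain_breaks(self) -> list[int]:
        """1-based indices i where the CA-CA distance i -> i+1 exceeds 4.2 A."""
        ca = self.coords("CA")
        gaps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        return [i + 1 for i, g in enumerate(gaps)
                if g > config.CHAIN_BREAK_CA_DISTANCE]


@dataclass
class ContactMap:
    """Symmetric set of residue index pairs (i < j, 1-based) within threshold."""

    L: int
    pairs: set[tuple[int, int]]
    threshold: float = config.CONTACT_THRESHOLD

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def neighbors(self, i: int) -> set[int]:
        return {b if a == i else a for a, b in self.pairs if i in (a, b)}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DecoyEnsemble:
    """Decoy structures with their energies and the low-energy selection."""

    decoys: list[ProteinStructure]
    energies: dict[str, float]
    selected: list[ProteinStructure] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [d.id for d in self.decoys if d.id not in self.energies]
        if missing:
            raise ValueError(f"decoys without energy: {missing[:5]}")


@dataclass
class Msa:
    """A multiple sequence alignment whose columns match the query row."""

    sequences: list[str]
    ids: list[str] = field(default_factory=list)

    @property
    def query(self) -> str:
        return self.sequences[0]

    @property
    def depth(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def column(self, c: int) -> str:
        """1-based column access."""
        return "".join(s[c - 1] for s in self.sequences)


@dataclass
class EvolutionaryScores:
    """Sparse pairwise coupling scores; absent pairs score 0.

    ``planted`` is generator metadata: the column pairs a synthetic
    alignment deliberately coupled (empty for external score files).
    """

    scores: dict[tuple[int, int], float]
    provenance: str = "external"
    planted: tuple = ()

    def get(self, i: int, j: int) -> float:
        return self.scores.get((min(i, j), max(i, j)), 0.0)

    def rescaled(self) -> "EvolutionaryScores":
        """Min-max rescale scores to [0, 1] (couplings scale differently
        between proteins and alignment depths)."""
        if not self.scores:
            return EvolutionaryScores({}, self.provenance)
        vals = np.array(list(self.scores.values()))
        lo, hi = vals.min(), vals.max()
        span = hi - lo if hi > lo else 1.0
        return EvolutionaryScores(
            {k: (v - lo) / span for k, v in self.scores.items()}, self.provenance
        )


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def read_structure(path: str | Path, chain: str | None = None) -> ProteinStructure:
    """Parse one chain of a PDB file into a ProteinStructure.

    altLoc conflicts resolve to the highest-occupancy conformer; HETATM
    records are ignored except selenomethionine (kept as M); residues
    lacking a CA atom are skipped with a warning.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure(path.stem, str(path)).get_models())
    chains = {c.id: c for c in model}
    if chain is not None:
        if chain not in chains:
            raise ValueError(f"chain {chain!r} not present in {path}")
        selected = chains[chain]
    else:
        selected = next(iter(chains.values()))

    residues: list[ResidueRecord] = []
    idx = 0
    for res in selected:
        het = res.id[0]
        if het not in (" ", "H_MSE"):
            continue
        name = res.get_resname()
        aa = "M" if name == "MSE" else seq1(name, custom_map={})
        if "CA" not in res:
            warnings.warn(f"{path.name}: residue {res.id} has no CA, skipped")
            continue
        idx += 1
        atoms = {}
        for atom in res:
            # Bio.PDB DisorderedAtom already selects the max-occupancy altloc
            atoms[atom.get_name()] = atom.get_coord().astype(float)
        residues.append(ResidueRecord(selected.id, idx, aa, atoms))
    if not residues:
        raise ValueError(f"no parseable residues in {path}")
    return ProteinStructure(path.stem, residues)


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_structure(s: ProteinStructure, path: str | Path) -> None:
    """Write a minimal single-chain PDB file (ATOM/TER/END)."""
    lines = []
    serial = 1
    for res in s.residues:
        res3 = _AA3[res.aa]
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in res.atoms:
                continue
            x, y, z = res.atoms[name]
            element = name[0]
            padded = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {padded} {res3:>3s} {res.chain_id}"
                f"{res.seq_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def contact_atom(res: ResidueRecord) -> np.ndarray:
    """Coordinate defining contacts: Cb, or Ca for glycine / missing Cb."""
    if "CA" not in res.atoms:
        raise ValueError(f"residue {res.seq_index} has no CA atom")
    if res.aa == "G" or "CB" not in res.atoms:
        if res.aa != "G" and "CB" not in res.atoms:
            warnings.warn(
                f"residue {res.seq_index} ({res.aa}) missing CB; using CA"
            )
        return res.atoms["CA"]
    return res.atoms["CB"]


def compute_contact_map(
    s: ProteinStructure,
    threshold: float = config.CONTACT_THRESHOLD,
    min_separation: int = config.GRAPH_MIN_SEPARATION,
) -> ContactMap:
    """All residue pairs whose contact atoms lie within ``threshold`` A."""
    if s.L < 2:
        raise ValueError("need at least two residues")
    xyz = s.contact_coords()
    dm = squareform(pdist(xyz))
    pairs = set()
    for i in range(s.L):
        for j in range(i + max(1, min_separation), s.L):
            if dm[i, j] <= threshold:
                pairs.add((i + 1, j + 1))
    return ContactMap(s.L, pairs, threshold)


# ---------------------------------------------------------------------------
# Alignments and score files
# ---------------------------------------------------------------------------


def read_msa(path: str | Path) -> Msa:
    """Read FASTA or A3M; lowercase insertion columns are removed so that
    every row aligns to the (first) query sequence."""
    ids: list[str] = []
    seqs: list[str] = []
    current: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if ids:
                seqs.append("".join(current))
            ids.append(line[1:].split()[0] if len(line) > 1 else "")
            current = []
        elif line.strip():
            current.append(line.strip())
    if ids:
        seqs.append("".join(current))
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    # a3m: lowercase letters are insertions relative to the query
    seqs = ["".join(c for c in s if not c.islower()) for s in seqs]
    n = len(seqs[0])
    bad = [i for i, s in enumerate(seqs) if len(s) != n]
    if bad:
        raise ValueError(f"ragged alignment rows (e.g. row {bad[0]}) in {path}")
    return Msa(seqs, ids)


def read_evolutionary_scores(
    path: str | Path, L: int | None = None
) -> EvolutionaryScores:
    """Read tab/space-separated ``i j score`` rows (1-based indices)."""
    scores: dict[tuple[int, int], float] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        i, j, score = int(fields[0]), int(fields[1]), float(fields[2])
        if L is not None and not (1 <= i <= L and 1 <= j <= L):
            raise ValueError(f"{path}:{ln}: index out of range 1..{L}")
        key = (min(i, j), max(i, j))
        if key in scores:
            warnings.warn(f"{path}:{ln}: duplicate pair {key}, last value wins")
        scores[key] = score
    return EvolutionaryScores(scores, provenance=str(path))


def read_energy_table(path: str | Path) -> dict[str, float]:
    """Read the sidecar ``decoy_id<TAB>energy`` table."""
    energies: dict[str, float] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"{path}:{ln}: expected 'decoy_id energy'")
        decoy_id, energy = fields
        if decoy_id in energies:
            raise ValueError(f"{path}:{ln}: duplicate decoy id {decoy_id!r}")
        energies[decoy_id] = float(energy)
    return energies


def select_low_energy(ens: DecoyEnsemble, fraction: float) -> DecoyEnsemble:
    """Retain the ceil(fraction * N) lowest-energy decoys.

    Ceiling guarantees at least one selected decoy; energy ties break by
    decoy id so selection is deterministic.
    """
    if not ens.decoys:
        raise ValueError("empty decoy ensemble")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = math.ceil(fraction * len(ens.decoys))
    order = sorted(ens.decoys, key=lambda d: (ens.energies[d.id], d.id))
    return DecoyEnsemble(ens.decoys, ens.energies, selected=order[:n])


# ---------------------------------------------------------------------------
# CASP RR contact lists
# ---------------------------------------------------------------------------


def write_rr(
    ranked: list[tuple[int, int, float]],
    path: str | Path,
    sequence: str | None = None,
) -> None:
    """Write ranked contacts in CASP RR dialect: optional ``PFRMAT RR`` and
    sequence header, then ``i j 0 8 score`` rows in descending score."""
    lines = ["PFRMAT RR"]
    if sequence:
        lines.append(sequence)
    for i, j, score in ranked:
        lines.append(f"{i} {j} 0 {config.CONTACT_THRESHOLD:g} {score:.6f}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rr(path: str | Path) -> list[tuple[int, int, float]]:
    """Parse an RR file back into (i, j, score) rows, preserving order."""
    out = []
    for line in Path(path).read_text().splitlines():
        fields = line.split()
        if len(fields) == 5 and fields[0].isdigit():
            out.append((int(fields[0]), int(fields[1]), float(fields[4])))
    return out
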