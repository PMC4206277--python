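"""Seeded synthetic natives, decoy ensembles, alignments and coupling scores.

The generator reproduces the statistical structure the prediction method
relies on, with no external software:

* **natives** — full-backbone chains (N, CA, C, O, CB) built residue by
  residue from ideal bond geometry, with helix/strand segments at ideal
  dihedrals and coil linkers chosen greedily to compact the chain, so
  the fold contains genuine medium- and long-range contacts; sequences
  are designed inside-out (hydrophobic core, polar surface), so native
  contacts are chemically favorable;
* **decoys** — samples around the native or around misfold attractor
  basins (alternative packings of the same chain), plus
  sequence-correlated Gaussian noise at one of three ladder amplitudes
  (very close / close / far), with a sidecar energy tracking the RMSD
  to the decoy's own basin; low-energy selection therefore retains
  mostly near-native decoys plus a minority of persistently misfolded
  ones whose recurring non-native contacts pure occurrence counting
  overrates;
* **alignments** — rows sampled from per-column profiles, with a chosen
  fraction of native contacts planted as jointly mutating column pairs,
  so APC-corrected mutual information recovers them at depth;
* **coupling scores** — the APC-MI of the generated alignment, standing
  in for an external evolutionary-coupling program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import config
from .features import mutual_information_matrix
from .structio import (ContactMap, DecoyEnsemble, EvolutionaryScores, Msa,
                       ProteinStructure, ResidueRecord, compute_contact_map,
                       write_structure)

__all__ = [
    "SyntheticProteinSpec",
    "SyntheticProtein",
    "make_recipe",
    "make_native",
    "make_misfolds",
    "make_decoys",
    "make_msa",
    "make_protein",
    "make_corpus",
    "write_protein_files",
]


@dataclass(frozen=True)
class SyntheticProteinSpec:
    """Study conditions of one synthetic protein.

    Defaults: 60 residues, 200 decoys at noise amplitudes 1/2/4 A
    (emulating decoys very close, relatively close and far from their
    basin), two misfold basins sampled by a third of the decoys,
    RMSD-tracking energies, a 500-row alignment, and up to 60% of the
    candidate native contacts planted as covarying column pairs
    (bounded by the disjoint-column matching, see make_msa).
    """

    L: int = 60
    n_decoys: int = 200
    sigma_ladder: tuple[float, ...] = (1.0, 2.0, 4.0)
    energy_slope: float = 1.0  # energy units per Angstrom RMSD
    energy_noise: float = 0.5
    ou_rho: float = 0.8  # along-chain correlation of coordinate noise
    n_misfolds: int = 2  # alternative compact conformations (decoy basins)
    misfold_weight: float = 1 / 3  # fraction of decoys drawn from them
    misfold_energy_offset: float = 0.4  # energy penalty of a misfold basin
    msa_depth: int = 500
    covary_fraction: float = 0.6
    mutation_rate: float = 0.3
    gap_rate: float = 0.02
    seed: int = 0


@dataclass
class SyntheticProtein:
    """One fully generated protein: structure, decoys, alignment, scores."""

    id: str
    native: ProteinStructure
    native_cm: ContactMap
    sequence: str
    ensemble: DecoyEnsemble
    msa: Msa
    evo: EvolutionaryScores
    spec: SyntheticProteinSpec


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------

_BOND_CN = 1.329
_BOND_NCA = 1.458
_BOND_CAC = 1.525
_BOND_CO = 1.231
_ANGLE_CACN = 116.2
_ANGLE_CNCA = 121.7
_ANGLE_NCAC = 111.2
_ANGLE_CACO = 120.5

_HELIX = (-57.0, -47.0)
_STRAND = (-120.0, 130.0)

_BURIED_AA = {"H": "ALM", "E": "VIF", "C": "AVL"}
_EXPOSED_AA = {"H": "EKQ", "E": "TSY", "C": "GSND"}


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Natural extension reference frame: position a new atom at the given
    internal coordinates relative to atoms a-b-c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_position(n, ca, c):
    """Ideal tetrahedral CB from the backbone frame (L-amino acid)."""
    return _place(n, c, ca, 1.53, 110.5, -122.6)


def make_recipe(L: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Random mixed topology: helix/strand segments joined by short coils."""
    recipe: list[tuple[str, int]] = []
    remaining = L
    kinds = ["H", "E"]
    k = int(rng.integers(0, 2))
    while remaining > 0:
        kind = kinds[k % 2]
        length = int(rng.integers(8, 13) if kind == "H" else rng.integers(5, 9))
        length = min(length, remaining)
        recipe.append((kind, length))
        remaining -= length
        if remaining <= 0:
            break
        coil = int(min(rng.integers(3, 6), remaining))
        recipe.append(("C", coil))
        remaining -= coil
        k += 1
    return recipe


def _expand_recipe(recipe: list[tuple[str, int]]) -> str:
    return "".join(kind * length for kind, length in recipe)


def _design_sequence(ss: str, ca: np.ndarray, rng: np.random.Generator) -> str:
    """Inside-out sequence design: hydrophobic residues at buried
    positions, polar/charged at exposed ones, per secondary-structure
    state.  This couples chemistry to the fold, so contacts of the
    designed (native) structure are chemically favorable while contacts
    of any alternative packing of the same sequence are not."""
    n_neigh = (
        (np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2) < 10.0).sum(1)
        - 1
    )
    cut = np.median(n_neigh)
    out = []
    for k, state in enumerate(ss):
        pool = (_BURIED_AA if n_neigh[k] > cut else _EXPOSED_AA)[state]
        out.append(pool[rng.integers(0, len(pool))])
    return "".join(out)


_COIL_BASINS = [(-140.0, 150.0), (-70.0, 140.0), (-100.0, 0.0), (60.0, 40.0)]


def _coil_candidates(rng: np.random.Generator, n: int = 6) -> list[float]:
    """Sample candidate dihedrals around the coil basins."""
    out = []
    for _ in range(n):
        basin = _COIL_BASINS[rng.integers(0, len(_COIL_BASINS))]
        out.append((basin[0] + rng.normal(0, 20), basin[1] + rng.normal(0, 20)))
    return out


def _extend(n_prev, ca_prev, c_prev, psi_prev: float, phi_k: float):
    """One NeRF step: backbone atoms of the next residue."""
    n_new = _place(n_prev, ca_prev, c_prev, _BOND_CN, _ANGLE_CACN, psi_prev)
    ca_new = _place(ca_prev, c_prev, n_new, _BOND_NCA, _ANGLE_CNCA, 180.0)
    c_new = _place(c_prev, n_new, ca_new, _BOND_CAC, _ANGLE_NCAC, phi_k)
    return n_new, ca_new, c_new


def _build_backbone(ss: str, rng: np.random.Generator):
    """One seeded build attempt; returns (N, CA, C arrays, psi list, phi list).

    Helix and strand residues use their ideal dihedrals.  At each coil
    step the candidate dihedral pair is scored by rolling the chain out
    through the next rigid segment (deterministic future dihedrals) and
    measuring how close the rolled-out CA ends up to the current
    centroid — one-step greed cannot see that a helix placed outward
    marches away for ten residues.  CA clashes are penalized.
    """
    L = len(ss)

    def allowed(kind: str) -> list[tuple[float, float]]:
        if kind == "H":
            return [_HELIX]
        if kind == "E":
            return [_STRAND]
        return _coil_candidates(rng)

    n_xyz = [np.array([0.0, 0.0, 0.0])]
    ca_xyz = [np.array([_BOND_NCA, 0.0, 0.0])]
    ang = math.radians(180.0 - _ANGLE_NCAC)
    c_xyz = [ca_xyz[0] + _BOND_CAC * np.array([math.cos(ang), math.sin(ang), 0.0])]
    psis: list[float] = []
    phis: list[float] = [0.0]  # phi of residue 1 is undefined

    def rollout_end(n0, ca0, c0, k: int, horizon: int = 12) -> np.ndarray:
        """Future CA position after extending through upcoming residues
        with default dihedrals (ideal for H/E, a fixed coil basin)."""
        n, ca, c = n0, ca0, c0
        for m in range(k + 1, min(L, k + 1 + horizon)):
            kind = ss[m]
            phi, psi = (_HELIX if kind == "H"
                        else _STRAND if kind == "E" else (-70.0, 140.0))
            prev_kind = ss[m - 1]
            psi_prev = (_HELIX[1] if prev_kind == "H"
                        else _STRAND[1] if prev_kind == "E" else 140.0)
            n, ca, c = _extend(n, ca, c, psi_prev, phi)
        return ca

    for k in range(1, L):
        prev_kind, kind = ss[k - 1], ss[k]
        choices = [
            (psi_prev, phi_k)
            for _, psi_prev in allowed(prev_kind)
            for phi_k, _ in allowed(kind)
        ]
        prior = np.array(ca_xyz)
        centroid = prior.mean(axis=0)
        best = None
        for psi_prev, phi_k in choices:
            n_new, ca_new, c_new = _extend(
                n_xyz[-1], ca_xyz[-1], c_xyz[-1], psi_prev, phi_k
            )
            score = float(np.linalg.norm(ca_new - centroid))
            if len(choices) > 1:
                end = rollout_end(n_new, ca_new, c_new, k)
                score += float(np.linalg.norm(end - centroid))
            if len(prior) > 2:
                min_d = float(np.min(np.linalg.norm(prior[:-1] - ca_new, axis=1)))
                if min_d < 4.0:
                    score += 1000.0
            if best is None or score < best[0]:
                best = (score, psi_prev, phi_k, n_new, ca_new, c_new)
        _, psi_prev, phi_k, n_new, ca_new, c_new = best
        psis.append(psi_prev)
        phis.append(phi_k)
        n_xyz.append(n_new)
        ca_xyz.append(ca_new)
        c_xyz.append(c_new)
    psis.append(180.0)  # psi of the last residue is undefined
    return n_xyz, ca_xyz, c_xyz, psis, phis


def make_native(
    spec: SyntheticProteinSpec,
    recipe: list[tuple[str, int]] | None = None,
    protein_id: str = "synthetic",
    n_restarts: int = 8,
    sequence: str | None = None,
) -> tuple[ProteinStructure, ContactMap, str]:
    """Build a compact native structure from ideal segment geometry.

    Several seeded build attempts are made and the one with the most
    medium/long-range contacts (ties: smallest radius of gyration) is
    kept, so the fold genuinely contains the contact classes the
    predictor is evaluated on.
    """
    rng = np.random.default_rng(spec.seed)
    if recipe is None:
        recipe = make_recipe(spec.L, rng)
    ss = _expand_recipe(recipe)
    if len(ss) != spec.L:
        raise ValueError(f"recipe covers {len(ss)} residues, expected {spec.L}")
    L = spec.L

    best = None
    for _ in range(n_restarts):
        n_xyz, ca_xyz, c_xyz, psis, phis = _build_backbone(ss, rng)
        ca = np.array(ca_xyz)
        dm = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
        n_distant = sum(
            1
            for i in range(L)
            for j in range(i + config.CANDIDATE_MIN_SEPARATION, L)
            if dm[i, j] <= config.CONTACT_THRESHOLD
        )
        rg = float(np.sqrt(((ca - ca.mean(0)) ** 2).sum(1).mean()))
        key = (-n_distant, rg)
        if best is None or key < best[0]:
            best = (key, n_xyz, ca_xyz, c_xyz, psis)
    _, n_xyz, ca_xyz, c_xyz, psis = best
    if sequence is None:
        sequence = _design_sequence(ss, np.array(ca_xyz), rng)

    residues = []
    for k in range(L):
        atoms = {
            "N": n_xyz[k],
            "CA": ca_xyz[k],
            "C": c_xyz[k],
            "O": _place(n_xyz[k], ca_xyz[k], c_xyz[k],
                        _BOND_CO, _ANGLE_CACO, psis[k] + 180.0),
        }
        if sequence[k] != "G":
            atoms["CB"] = _cb_position(n_xyz[k], ca_xyz[k], c_xyz[k])
        residues.append(ResidueRecord("A", k + 1, sequence[k], atoms))
    native = ProteinStructure(protein_id, residues)
    return native, compute_contact_map(native), sequence


# ---------------------------------------------------------------------------
# Decoys
# ---------------------------------------------------------------------------


def _ou_displacements(L: int, sigma: float, rho: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-residue 3D noise, AR(1)-correlated along the sequence so local
    geometry degrades gracefully."""
    x = np.zeros((L, 3))
    x[0] = rng.normal(0, sigma, 3)
    for k in range(1, L):
        x[k] = rho * x[k - 1] + math.sqrt(1 - rho ** 2) * rng.normal(0, sigma, 3)
    return x


def make_misfolds(
    native: ProteinStructure,
    spec: SyntheticProteinSpec,
    recipe: list[tuple[str, int]],
) -> list[ProteinStructure]:
    """Alternative compact conformations of the same chain.

    A misfold keeps the secondary-structure segments and sequence of the
    native but packs them differently, so its contact map shares local
    contacts with the native while differing at longer range — the
    synthetic analogue of a systematically misfolded low-energy decoy
    basin."""
    misfolds = []
    for m in range(spec.n_misfolds):
        alt_spec = SyntheticProteinSpec(
            **{**spec.__dict__, "seed": spec.seed + 7919 * (m + 1)}
        )
        alt, _, _ = make_native(
            alt_spec, recipe=recipe, protein_id=f"{native.id}_mis{m}",
            n_restarts=2, sequence=native.sequence,
        )
        misfolds.append(alt)
    return misfolds


def make_decoys(
    native: ProteinStructure,
    spec: SyntheticProteinSpec,
    misfolds: list[ProteinStructure] | None = None,
    recipe: list[tuple[str, int]] | None = None,
) -> DecoyEnsemble:
    """Sample decoys around the native and (optionally) misfold basins.

    Each decoy is one basin conformation plus sequence-correlated
    Gaussian noise at a ladder amplitude.  Energy tracks the RMSD to the
    decoy's own basin (plus a constant penalty for misfold basins and
    Gaussian noise), so low-energy selection retains mostly near-native
    decoys with a minority of persistently misfolded ones — occurrence
    frequency alone therefore overrates the misfolds' non-native
    contacts."""
    rng = np.random.default_rng(spec.seed + 1)
    if misfolds is None and spec.n_misfolds > 0:
        if recipe is None:
            recipe = make_recipe(spec.L, np.random.default_rng(spec.seed))
        misfolds = make_misfolds(native, spec, recipe)
    basins = [native] + (misfolds or [])
    decoys = []
    energies = {}
    width = len(str(spec.n_decoys))
    for d in range(spec.n_decoys):
        if len(basins) > 1 and rng.random() < spec.misfold_weight:
            b = 1 + int(rng.integers(0, len(basins) - 1))
        else:
            b = 0
        basin = basins[b]
        sigma = spec.sigma_ladder[int(rng.integers(0, len(spec.sigma_ladder)))]
        disp = _ou_displacements(native.L, sigma, spec.ou_rho, rng)
        residues = []
        for k, res in enumerate(basin.residues):
            atoms = {name: xyz + disp[k] for name, xyz in res.atoms.items()}
            residues.append(ResidueRecord(res.chain_id, res.seq_index, res.aa,
                                          atoms))
        decoy_id = f"{native.id}_d{d:0{width}d}"
        decoys.append(ProteinStructure(decoy_id, residues))
        rmsd = float(np.sqrt((disp ** 2).sum(axis=1).mean()))
        energies[decoy_id] = (
            spec.energy_slope * rmsd
            + (spec.misfold_energy_offset if b else 0.0)
            + rng.normal(0, spec.energy_noise)
        )
    return DecoyEnsemble(decoys, energies)


# ---------------------------------------------------------------------------
# Alignments and planted couplings
# ---------------------------------------------------------------------------


def make_msa(
    sequence: str,
    native_cm: ContactMap,
    spec: SyntheticProteinSpec,
) -> tuple[Msa, EvolutionaryScores]:
    """Sample an alignment with covariation planted on native contacts.

    Every column mutates independently within a small per-column letter
    pool, except the planted pairs: there the two columns switch jointly
    between two letter combinations, which APC-corrected mutual
    information recovers given depth.  The returned scores are exactly
    that APC-MI matrix (non-negative entries), standing in for an
    external coupling program.  A depth-1 alignment yields no scores.
    """
    rng = np.random.default_rng(spec.seed + 2)
    L = len(sequence)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    candidates = sorted(
        (i, j) for i, j in native_cm.pairs
        if j - i >= config.CANDIDATE_MIN_SEPARATION
    )
    # plant on a disjoint column matching: a column that belongs to two
    # planted pairs would have its joint states overwritten and the
    # coupling destroyed
    n_plant = int(round(spec.covary_fraction * len(candidates)))
    planted: list[tuple[int, int]] = []
    used: set[int] = set()
    for k in rng.permutation(len(candidates)):
        i, j = candidates[k]
        if i in used or j in used:
            continue
        planted.append((i, j))
        used |= {i, j}
        if len(planted) >= n_plant:
            break
    planted.sort()
    planted_cols = set(used)

    # per-column substitution pools (query letter + 3 alternatives)
    pools = []
    for c in range(L):
        alts = rng.choice([a for a in alphabet if a != sequence[c]], 3,
                          replace=False)
        pools.append(sequence[c] + "".join(alts))
    # joint states of planted pairs: (query_i, query_j) and a swapped pair
    alt_state = {}
    for i, j in planted:
        alt_state[(i, j)] = (pools[i - 1][1], pools[j - 1][1])

    rows = [sequence]
    for _ in range(spec.msa_depth - 1):
        row = list(sequence)
        for c in range(L):
            if (c + 1) in planted_cols:
                continue
            if rng.random() < spec.mutation_rate:
                row[c] = pools[c][rng.integers(0, 4)]
        for i, j in planted:
            if rng.random() < 0.5:
                row[i - 1], row[j - 1] = alt_state[(i, j)]
            # 10% independent noise on planted columns
            if rng.random() < 0.1:
                row[i - 1] = pools[i - 1][rng.integers(0, 4)]
            if rng.random() < 0.1:
                row[j - 1] = pools[j - 1][rng.integers(0, 4)]
        for c in range(L):
            if rng.random() < spec.gap_rate:
                row[c] = "-"
        rows.append("".join(row))
    msa = Msa(rows, [f"seq{k}" for k in range(len(rows))])

    if msa.depth < 2:
        return msa, EvolutionaryScores({}, provenance="synthetic")
    _, apc = mutual_information_matrix(msa)
    scores = {
        (i, j): float(apc[i - 1, j - 1])
        for i in range(1, L + 1)
        for j in range(i + 1, L + 1)
        if apc[i - 1, j - 1] > 0
    }
    return msa, EvolutionaryScores(scores, provenance="synthetic",
                                   planted=tuple(planted))


# ---------------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------------


def make_protein(spec: SyntheticProteinSpec, protein_id: str) -> SyntheticProtein:
    """Generate one complete synthetic protein."""
    recipe = make_recipe(spec.L, np.random.default_rng(spec.seed))
    native, cm, sequence = make_native(spec, recipe=recipe,
                                       protein_id=protein_id)
    ensemble = make_decoys(native, spec, recipe=recipe)
    msa, evo = make_msa(sequence, cm, spec)
    return SyntheticProtein(protein_id, native, cm, sequence, ensemble, msa,
                            evo, spec)


def make_corpus(
    n_proteins: int,
    template: SyntheticProteinSpec = SyntheticProteinSpec(),
    seed: int = 0,
    test_fraction: float = 1 / 3,
) -> tuple[list[SyntheticProtein], list[SyntheticProtein]]:
    """n independent proteins split into disjoint train/test sets."""
    if n_proteins < 6:
        raise ValueError("need at least 6 proteins")
    proteins = []
    for k in range(n_proteins):
        spec = SyntheticProteinSpec(
            **{**template.__dict__, "seed": seed * 10_000 + k}
        )
        proteins.append(make_protein(spec, protein_id=f"syn{k:03d}"))
    n_test = max(1, int(round(test_fraction * n_proteins)))
    return proteins[:-n_test], proteins[-n_test:]


def write_protein_files(p: SyntheticProtein, out_dir: str | Path) -> None:
    """Write one protein to disk in the external formats the tool reads:
    native PDB, decoy PDBs + energy TSV, A3M alignment, score TSV."""
    out = Path(out_dir)
    decoy_dir = out / f"{p.id}_decoys"
    decoy_dir.mkdir(parents=True, exist_ok=True)
    write_structure(p.native, out / f"{p.id}_native.pdb")
    for d in p.ensemble.decoys:
        write_structure(d, decoy_dir / f"{d.id}.pdb")
    energy_lines = [f"{d.id}\t{p.ensemble.energies[d.id]:.6f}"
                    for d in p.ensemble.decoys]
    (out / f"{p.id}_energies.tsv").write_text("\n".join(energy_lines) + "\n")
    msa_lines = []
    for k, row in enumerate(p.msa.sequences):
        msa_lines.append(f">{p.msa.ids[k] if p.msa.ids else k}")
        msa_lines.append(row)
    (out / f"{p.id}.a3m").write_text("\n".join(msa_lines) + "\n")
    score_lines = [f"{i}\t{j}\t{s:.6f}" for (i, j), s in sorted(p.evo.scores.items())]
    (out / f"{p.id}_evo.tsv").write_text("\n".join(score_lines) + "\n")
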