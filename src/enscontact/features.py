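"""Structure annotation and the 238-input contact feature encoding.

A candidate contact (i, j) observed in one decoy is encoded as a fixed
vector of 238 inputs in seven groups:

====================  =====
pairwise                 49
graph topology        2x 10
graph spectrum        2x  5
single node           2x 10
node label statistics 2x 43
edge label statistics 2x 12
whole protein            29
====================  =====

Graph-based groups are evaluated once on the shared neighborhood graph and
once on the immediate neighborhood graph, which is why they appear twice.
Group sizes are a schema contract: any mismatch raises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from . import config
from .graphs import ContactGraph
from .structio import ContactMap, Msa, ProteinStructure

__all__ = [
    "NodeLabels",
    "EdgeLabels",
    "Labels",
    "EnsembleContext",
    "FeatureVector",
    "assign_secondary_structure",
    "compute_sasa",
    "detect_hbonds",
    "solvation_energies",
    "conservation_profile",
    "mutual_information_matrix",
    "build_labels",
    "build_ensemble_context",
    "pairwise_features",
    "topology_features",
    "spectrum_features",
    "single_node_features",
    "node_label_statistics",
    "edge_label_statistics",
    "whole_protein_features",
    "assemble_feature_vector",
    "feature_schema",
    "GROUP_SIZES",
]

GROUP_SIZES = {
    "pairwise": 49,
    "topology": 10,
    "spectrum": 5,
    "single_node": 10,
    "node_stats": 43,
    "edge_stats": 12,
    "whole_protein": 29,
}

SCHEMA_VERSION = "1.0"
TOTAL_INPUTS = 238

_CHEM = config.load_chem_classes()
_MAX_SASA = config.load_max_sasa()
_SIGMA = config.load_solvation_sigma()
_POTENTIAL = config.load_contact_potential()
_CHEM_INDEX = {c: k for k, c in enumerate(config.CHEM_CLASSES)}
_SS7_INDEX = {c: k for k, c in enumerate(config.SS7_CLASSES)}
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(s: ProteinStructure) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (phi, psi) in degrees; NaN where undefined."""
    phi = np.full(s.L, np.nan)
    psi = np.full(s.L, np.nan)
    res = s.residues
    for k in range(s.L):
        a = res[k].atoms
        if k > 0:
            prev = res[k - 1].atoms
            if all(n in prev for n in ("C",)) and all(n in a for n in ("N", "CA", "C")):
                phi[k] = _dihedral(prev["C"], a["N"], a["CA"], a["C"])
        if k < s.L - 1:
            nxt = res[k + 1].atoms
            if all(n in a for n in ("N", "CA", "C")) and "N" in nxt:
                psi[k] = _dihedral(a["N"], a["CA"], a["C"], nxt["N"])
    return phi, psi


# ---------------------------------------------------------------------------
# Secondary structure (dihedral + hydrogen-bond heuristic)
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Keep only True-runs of at least min_len."""
    out = np.zeros_like(mask)
    k = 0
    n = len(mask)
    while k < n:
        if mask[k]:
            j = k
            while j < n and mask[j]:
                j += 1
            if j - k >= min_len:
                out[k:j] = True
            k = j
        else:
            k += 1
    return out


def assign_secondary_structure(s: ProteinStructure) -> tuple[str, str]:
    """7-state and 3-state secondary structure strings.

    Helix (H): phi in [-90, -30], psi in [-77, -17], runs of >= 4.
    Strand (E): phi in [-170, -70], psi in [90, 180] or [-180, -170],
    runs of >= 3.  3-10 helix (G) and pi helix (I) are flagged by (i, i+3)
    and (i, i+5) backbone hydrogen bonds on otherwise helical dihedrals;
    (i, i+3) bonds without helical dihedrals mark turns (T).  Everything
    else is coil (C).  ss3 collapses H/G/I -> H and E/B -> E.
    """
    if s.L < 3:
        return "C" * s.L, "C" * s.L
    phi, psi = backbone_dihedrals(s)
    helix_like = (
        (phi >= -90) & (phi <= -30) & (psi >= -77) & (psi <= -17)
    )
    strand_like = (
        (phi >= -170) & (phi <= -70)
        & (((psi >= 90) & (psi <= 180)) | ((psi >= -180) & (psi <= -170)))
    )
    helix = _runs(np.nan_to_num(helix_like, nan=0).astype(bool), 4)
    strand = _runs(np.nan_to_num(strand_like, nan=0).astype(bool), 3)

    hbonds = detect_hbonds(s)
    sep3 = {i for i, j in hbonds if abs(j - i) == 3} | {
        j for i, j in hbonds if abs(j - i) == 3
    }
    sep5 = {i for i, j in hbonds if abs(j - i) == 5} | {
        j for i, j in hbonds if abs(j - i) == 5
    }

    ss7 = []
    for k in range(s.L):
        pos = k + 1
        if helix[k]:
            ss7.append("H")
        elif strand[k]:
            ss7.append("E")
        elif helix_like[k] and pos in sep3:
            ss7.append("G")
        elif helix_like[k] and pos in sep5:
            ss7.append("I")
        elif pos in sep3:
            ss7.append("T")
        else:
            ss7.append("C")
    ss7 = "".join(ss7)
    ss3 = ss7.translate(str.maketrans("HGIEBT", "HHHEEC"))
    return ss7, ss3


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley sphere sampling)
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _atom_table(s: ProteinStructure):
    coords, radii, res_idx, names = [], [], [], []
    for k, res in enumerate(s.residues):
        for name, xyz in res.atoms.items():
            coords.append(xyz)
            radii.append(config.VDW_RADII.get(name[0], config.VDW_DEFAULT))
            res_idx.append(k)
            names.append((res.aa, name))
    return np.array(coords), np.array(radii), np.array(res_idx), names


def compute_sasa(
    s: ProteinStructure,
    probe: float = config.SASA_PROBE_RADIUS,
    n_points: int = config.SASA_N_POINTS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shrake-Rupley SASA.

    Returns (per-residue SASA, per-residue RSA clamped to [0, 1.2],
    per-atom SASA).  RSA divides by the per-residue theoretical maximum.
    """
    coords, radii, res_idx, _ = _atom_table(s)
    n_atoms = len(coords)
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    expanded = radii + probe
    atom_sasa = np.zeros(n_atoms)
    rmax = expanded.max()
    for a in range(n_atoms):
        surface = coords[a] + expanded[a] * pts
        neighbors = [b for b in tree.query_ball_point(coords[a], expanded[a] + rmax)
                     if b != a]
        if neighbors:
            nb = np.array(neighbors)
            d = np.linalg.norm(surface[:, None, :] - coords[nb][None, :, :], axis=2)
            accessible = np.all(d >= expanded[nb][None, :], axis=1)
        else:
            accessible = np.ones(n_points, dtype=bool)
        atom_sasa[a] = (
            accessible.mean() * 4.0 * np.pi * expanded[a] ** 2
        )
    res_sasa = np.zeros(s.L)
    np.add.at(res_sasa, res_idx, atom_sasa)
    max_sasa = np.array([_MAX_SASA.get(r.aa, _MAX_SASA["X"]) for r in s.residues])
    rsa = np.clip(res_sasa / max_sasa, 0.0, 1.2)
    return res_sasa, rsa, atom_sasa


def solvation_energies(s: ProteinStructure, atom_sasa: np.ndarray) -> np.ndarray:
    """Per-residue free solvation energy: sum over atoms of sigma * SASA."""
    charged_o = {("D", "OD1"), ("D", "OD2"), ("E", "OE1"), ("E", "OE2")}
    charged_n = {("K", "NZ"), ("R", "NE"), ("R", "NH1"), ("R", "NH2"),
                 ("H", "ND1"), ("H", "NE2")}
    _, _, res_idx, names = _atom_table(s)
    energies = np.zeros(s.L)
    for a, (aa, name) in enumerate(names):
        el = name[0]
        if el == "S":
            sigma = _SIGMA["S"]
        elif name == "OXT" or (aa, name) in charged_o:
            sigma = _SIGMA["O-"]
        elif (aa, name) in charged_n:
            sigma = _SIGMA["N+"]
        elif el in ("N", "O"):
            sigma = _SIGMA["N/O"]
        else:
            sigma = _SIGMA["C"]
        energies[res_idx[a]] += sigma * atom_sasa[a]
    return energies


def detect_hbonds(s: ProteinStructure) -> set[tuple[int, int]]:
    """Backbone hydrogen bonds: donor N of residue i within 3.5 A of
    acceptor O of residue j, |i - j| >= 2.  Returns (donor, acceptor)
    pairs of 1-based indices."""
    n_xyz = s.coords("N")
    o_xyz = s.coords("O")
    bonds: set[tuple[int, int]] = set()
    ok_n = ~np.isnan(n_xyz[:, 0])
    ok_o = ~np.isnan(o_xyz[:, 0])
    for i in np.nonzero(ok_n)[0]:
        d = np.linalg.norm(o_xyz - n_xyz[i], axis=1)
        for j in np.nonzero(ok_o & (d <= config.HBOND_NO_CUTOFF))[0]:
            if abs(int(i) - int(j)) >= config.HBOND_MIN_SEPARATION:
                bonds.add((int(i) + 1, int(j) + 1))
    return bonds


# ---------------------------------------------------------------------------
# Alignment-derived annotations
# ---------------------------------------------------------------------------


def _henikoff_weights(rows: np.ndarray) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff)."""
    depth, n_cols = rows.shape
    w = np.zeros(depth)
    for c in range(n_cols):
        col = rows[:, c]
        symbols, counts = np.unique(col, return_counts=True)
        k = len(symbols)
        cnt = dict(zip(symbols.tolist(), counts.tolist()))
        for r in range(depth):
            w[r] += 1.0 / (k * cnt[col[r]])
    total = w.sum()
    return w / total * depth if total > 0 else np.ones(depth)


def conservation_profile(m: Msa) -> tuple[np.ndarray, np.ndarray]:
    """Per-column conservation 1 - H/log(20) and its +/-2-column mean.

    Columns are smoothed by adding one pseudo-observation per amino acid
    type already present, so single-symbol columns have zero entropy and
    conservation exactly 1 (a depth-1 alignment is fully conserved).
    """
    rows = np.array([list(s) for s in m.sequences])
    weights = _henikoff_weights(rows)
    n_cols = m.n_columns
    cons = np.zeros(n_cols)
    for c in range(n_cols):
        col = rows[:, c]
        counts: dict[str, float] = {}
        for r, a in enumerate(col):
            if a in ("-", ".", "X"):
                continue
            counts[a] = counts.get(a, 0.0) + weights[r]
        if not counts:
            cons[c] = 0.0
            continue
        vals = np.array(list(counts.values())) + 1.0  # pseudocount per type
        p = vals / vals.sum()
        h = -np.sum(p * np.log(p))
        cons[c] = max(0.0, 1.0 - h / np.log(20.0))
    neigh = np.array(
        [cons[max(0, c - 2): c + 3].mean() for c in range(n_cols)]
    )
    return cons, neigh


_SYMBOLS = _AA_ORDER + "-"


def mutual_information_matrix(m: Msa) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise column mutual information and its APC-corrected form.

    MI is computed over 21 symbols (20 amino acids + gap) with a
    pseudocount of 0.05 per joint cell.  The average product correction
    subtracts mean_i(MI) * mean_j(MI) / mean(MI) to remove background
    covariation.  Depth < 2 yields all-zero matrices.
    """
    n = m.n_columns
    mi = np.zeros((n, n))
    if m.depth < 2:
        return mi, mi.copy()
    index = {c: k for k, c in enumerate(_SYMBOLS)}
    enc = np.array(
        [[index.get(c, 20) for c in row] for row in m.sequences], dtype=np.int64
    )
    ns = len(_SYMBOLS)
    lam = config.MI_PSEUDOCOUNT
    for a in range(n):
        for b in range(a + 1, n):
            joint = np.full((ns, ns), lam)
            np.add.at(joint, (enc[:, a], enc[:, b]), 1.0)
            joint /= joint.sum()
            pa = joint.sum(axis=1)
            pb = joint.sum(axis=0)
            val = np.sum(joint * np.log(joint / np.outer(pa, pb)))
            mi[a, b] = mi[b, a] = max(0.0, val)
    if n < 2:
        return mi, mi.copy()
    off = ~np.eye(n, dtype=bool)
    col_mean = mi.sum(axis=1) / (n - 1)
    grand = mi[off].mean()
    apc = mi - np.outer(col_mean, col_mean) / grand if grand > 0 else mi.copy()
    np.fill_diagonal(apc, 0.0)
    return mi, apc


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------


@dataclass
class NodeLabels:
    """Complete annotation of one residue in one decoy."""

    aa: str
    chem_class: str
    ss3: str
    ss7: str
    rsa: float
    buried: bool
    hbond_count: int
    solvation_energy: float
    conservation: float
    neigh_conservation: float
    coord: np.ndarray


@dataclass
class EdgeLabels:
    """Annotation of one contact edge in one decoy."""

    mi: float
    apc_mi: float
    contact_potential: float
    distance: float


@dataclass
class Labels:
    """Vectorized node/edge annotations for one decoy.

    ``node(i)`` / ``edge(i, j)`` give per-item views; the array attributes
    back the feature encoders.
    """

    aa: list[str]
    chem_idx: np.ndarray
    ss7: str
    ss3: str
    rsa: np.ndarray
    hbond_count: np.ndarray
    solvation: np.ndarray
    conservation: np.ndarray
    neigh_conservation: np.ndarray
    coords: np.ndarray
    mi: np.ndarray
    apc_mi: np.ndarray
    hbonds: set[tuple[int, int]]

    def node(self, i: int) -> NodeLabels:
        k = i - 1
        return NodeLabels(
            aa=self.aa[k],
            chem_class=config.CHEM_CLASSES[self.chem_idx[k]],
            ss3=self.ss3[k],
            ss7=self.ss7[k],
            rsa=float(self.rsa[k]),
            buried=bool(self.rsa[k] < config.BURIED_RSA_THRESHOLD),
            hbond_count=int(self.hbond_count[k]),
            solvation_energy=float(self.solvation[k]),
            conservation=float(self.conservation[k]),
            neigh_conservation=float(self.neigh_conservation[k]),
            coord=self.coords[k],
        )

    def potential(self, i: int, j: int) -> float:
        a, b = self.aa[i - 1], self.aa[j - 1]
        return _POTENTIAL.get((a, b), _POTENTIAL.get((b, a), 0.0))

    def edge(self, i: int, j: int) -> EdgeLabels:
        return EdgeLabels(
            mi=float(self.mi[i - 1, j - 1]),
            apc_mi=float(self.apc_mi[i - 1, j - 1]),
            contact_potential=self.potential(i, j),
            distance=float(np.linalg.norm(self.coords[i - 1] - self.coords[j - 1])),
        )

    def has_hbond(self, i: int, j: int) -> bool:
        return (i, j) in self.hbonds or (j, i) in self.hbonds


def compute_msa_stats(msa: Msa) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(conservation, neighborhood conservation, MI, APC-MI) of one
    alignment — computed once per protein and shared across its decoys."""
    cons, neigh = conservation_profile(msa)
    mi, apc = mutual_information_matrix(msa)
    return cons, neigh, mi, apc


def build_labels(
    s: ProteinStructure,
    msa: Msa | None = None,
    msa_stats: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> Labels:
    """Annotate one decoy: secondary structure, SASA/RSA, hydrogen bonds,
    solvation energies and (when an alignment is given) conservation and
    mutual information.  ``msa_stats`` short-circuits the alignment
    computations with a precomputed per-protein result."""
    ss7, ss3 = assign_secondary_structure(s)
    _, rsa, atom_sasa = compute_sasa(s)
    solv = solvation_energies(s, atom_sasa)
    hbonds = detect_hbonds(s)
    hb_count = np.zeros(s.L, dtype=int)
    for i, j in hbonds:
        hb_count[i - 1] += 1
        hb_count[j - 1] += 1
    if msa_stats is not None:
        cons, neigh, mi, apc = msa_stats
        if len(cons) != s.L:
            raise ValueError("precomputed alignment stats do not match L")
    elif msa is not None:
        if msa.n_columns != s.L:
            raise ValueError(
                f"alignment has {msa.n_columns} columns but structure has {s.L}"
            )
        cons, neigh = conservation_profile(msa)
        mi, apc = mutual_information_matrix(msa)
    else:
        cons = np.ones(s.L)
        neigh = np.ones(s.L)
        mi = np.zeros((s.L, s.L))
        apc = np.zeros((s.L, s.L))
    chem_idx = np.array(
        [_CHEM_INDEX[_CHEM.get(r.aa, "polar")] for r in s.residues]
    )
    return Labels(
        aa=[r.aa for r in s.residues],
        chem_idx=chem_idx,
        ss7=ss7,
        ss3=ss3,
        rsa=rsa,
        hbond_count=hb_count,
        solvation=solv,
        conservation=cons,
        neigh_conservation=neigh,
        coords=s.contact_coords(),
        mi=mi,
        apc_mi=apc,
        hbonds=hbonds,
    )


@dataclass
class EnsembleContext:
    """Per-pair distance statistics over the selected decoys."""

    mean_dist: np.ndarray
    sd_dist: np.ndarray
    counts: np.ndarray
    N: int

    def occurrence(self, i: int, j: int) -> int:
        return int(self.counts[i - 1, j - 1])

    def frequency(self, i: int, j: int) -> float:
        return float(self.counts[i - 1, j - 1]) / self.N


def build_ensemble_context(
    decoys: list[ProteinStructure],
    threshold: float = config.CONTACT_THRESHOLD,
) -> EnsembleContext:
    """Distance mean/sd and contact occurrence counts over decoys."""
    if not decoys:
        raise ValueError("no decoys")
    dms = np.array([squareform(pdist(d.contact_coords())) for d in decoys])
    counts = (dms <= threshold).sum(axis=0)
    np.fill_diagonal(counts, 0)
    return EnsembleContext(
        mean_dist=dms.mean(axis=0),
        sd_dist=dms.std(axis=0),
        counts=counts,
        N=len(decoys),
    )


# ---------------------------------------------------------------------------
# Feature groups
# ---------------------------------------------------------------------------


def _one_hot(index: int, n: int) -> list[float]:
    v = [0.0] * n
    v[index] = 1.0
    return v


def _bin_index(x: float, inner_edges: tuple[float, ...]) -> int:
    return int(np.digitize(x, inner_edges))


def _distribution(values, inner_edges) -> list[float]:
    n_bins = len(inner_edges) + 1
    if len(values) == 0:
        return [0.0] * n_bins
    hist = np.zeros(n_bins)
    for v in values:
        hist[_bin_index(v, inner_edges)] += 1
    return list(hist / hist.sum())


def _entropy(dist) -> float:
    p = np.asarray(dist)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) if p.size else 0.0


def pairwise_features(
    i: int, j: int, labels: Labels, ens: EnsembleContext, L: int
) -> np.ndarray:
    """49 residue-pair inputs: chemistry, secondary structure, burial,
    solvation, hydrogen bonding, sequence separation, terminal distances,
    contact potential, decoy and ensemble distances, mutual information."""
    ni, nj = labels.node(i), labels.node(j)
    v: list[float] = []
    for n in (ni, nj):
        v += _one_hot(_CHEM_INDEX[n.chem_class], 7)
    for n in (ni, nj):
        v += _one_hot(config.SS3_CLASSES.index(n.ss3), 3)
    v += [ni.rsa, nj.rsa]
    v += [float(ni.buried), float(nj.buried)]
    v += [ni.solvation_energy, nj.solvation_energy]
    v += [config.KYTE_DOOLITTLE[ni.aa], config.KYTE_DOOLITTLE[nj.aa]]
    v += [float(labels.has_hbond(i, j))]
    v += [float(ni.hbond_count), float(nj.hbond_count)]
    sep = abs(j - i)
    v += [float(sep)]
    v += _one_hot(_bin_index(sep, config.SEPARATION_BIN_EDGES), 4)
    v += [float(i - 1), float(L - i), float(j - 1), float(L - j)]
    e = labels.edge(i, j)
    v += [e.contact_potential]
    v += _one_hot(_bin_index(e.contact_potential, config.POTENTIAL_BIN_EDGES), 3)
    v += [e.distance]
    v += [float(ens.mean_dist[i - 1, j - 1]), float(ens.sd_dist[i - 1, j - 1])]
    v += [e.mi, e.apc_mi]
    assert len(v) == GROUP_SIZES["pairwise"]
    return np.array(v)


def topology_features(g: ContactGraph) -> np.ndarray:
    """10 descriptors of the graph topology (see docstring order).

    Disconnected graphs compute radius/diameter/eccentricity on the
    largest connected component; centralities follow the standard
    normalized definitions.
    """
    G = g.graph
    n = G.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if n == 1:
        return np.array([1.0] + [0.0] * 9)
    deg_c = float(np.mean(list(nx.degree_centrality(G).values())))
    clo_c = float(np.mean(list(nx.closeness_centrality(G).values())))
    bet_c = float(np.mean(list(nx.betweenness_centrality(G).values())))
    comp = max(nx.connected_components(G), key=lambda c: (len(c), -min(c)))
    sub = G.subgraph(comp)
    if sub.number_of_nodes() > 1:
        ecc = nx.eccentricity(sub)
        radius = float(min(ecc.values()))
        diameter = float(max(ecc.values()))
        avg_ecc = float(np.mean(list(ecc.values())))
    else:
        radius = diameter = avg_ecc = 0.0
    end_points = float(sum(1 for _, d in G.degree() if d == 1))
    clustering = float(nx.average_clustering(G))
    out = np.array([
        float(n),
        float(G.number_of_edges()),
        deg_c,
        clo_c,
        bet_c,
        radius,
        diameter,
        avg_ecc,
        end_points,
        clustering,
    ])
    assert out.size == GROUP_SIZES["topology"]
    return out


def spectrum_features(g: ContactGraph, tol: float = 1e-8) -> np.ndarray:
    """5 adjacency-spectrum descriptors: two largest eigenvalues, number
    of distinct eigenvalues, trace (sum), and graph energy (sum of
    absolute eigenvalues)."""
    n = len(g)
    if n == 0:
        raise ValueError("empty graph")
    if n == 1:
        return np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    a = nx.to_numpy_array(g.graph, nodelist=sorted(g.nodes))
    eig = np.sort(np.linalg.eigvalsh(a))[::-1]
    distinct = 1
    for k in range(1, len(eig)):
        if abs(eig[k] - eig[k - 1]) > tol:
            distinct += 1
    out = np.array([eig[0], eig[1], float(distinct), eig.sum(), np.abs(eig).sum()])
    assert out.size == GROUP_SIZES["spectrum"]
    return out


def single_node_features(
    i: int, j: int, g: ContactGraph, labels: Labels
) -> np.ndarray:
    """10 anchor-residue inputs: degree, closeness, betweenness,
    conservation and neighborhood conservation for i, then for j."""
    G = g.graph
    if i not in G or j not in G:
        raise ValueError(f"anchors ({i},{j}) not in graph")
    n = G.number_of_nodes()
    clo = nx.closeness_centrality(G) if n > 1 else {i: 0.0, j: 0.0}
    bet = nx.betweenness_centrality(G) if n > 2 else {x: 0.0 for x in G}
    v = []
    for x in (i, j):
        nl = labels.node(x)
        v += [
            float(G.degree(x)),
            float(clo.get(x, 0.0)),
            float(bet.get(x, 0.0)),
            nl.conservation,
            nl.neigh_conservation,
        ]
    assert len(v) == GROUP_SIZES["single_node"]
    return np.array(v)


def node_label_statistics(g: ContactGraph, labels: Labels) -> np.ndarray:
    """43 statistics over the node labels of the graph: class and
    secondary-structure distributions, burial, hydrogen bonding,
    solvation, label entropies, neighborhood impurity, geometry around
    the centroid, and conservation summaries."""
    nodes = sorted(g.nodes)
    nls = [labels.node(x) for x in nodes]
    chem_dist = np.zeros(7)
    for nl in nls:
        chem_dist[_CHEM_INDEX[nl.chem_class]] += 1
    chem_dist /= chem_dist.sum()
    ss7_dist = np.zeros(7)
    for nl in nls:
        ss7_dist[_SS7_INDEX[nl.ss7]] += 1
    ss7_dist /= ss7_dist.sum()
    rsa_vals = [nl.rsa for nl in nls]
    rsa_bins = _distribution(rsa_vals, config.RSA_BIN_EDGES)
    frac_hb = float(np.mean([nl.hbond_count > 0 for nl in nls]))
    mean_hb = float(np.mean([nl.hbond_count for nl in nls]))
    solv = [nl.solvation_energy for nl in nls]
    solv_bins = _distribution(solv, config.SOLVATION_BIN_EDGES)
    impurity = _neighborhood_impurity(g, labels)
    coords = np.array([nl.coord for nl in nls])
    centroid = coords.mean(axis=0)
    d_cen = np.linalg.norm(coords - centroid, axis=1)
    cons = np.array([nl.conservation for nl in nls])
    ncons = np.array([nl.neigh_conservation for nl in nls])
    if g.anchor is not None:
        ai, aj = g.anchor
        local = float(
            np.mean([min(abs(x - ai), abs(x - aj)) <= 2 for x in nodes])
        )
    else:
        local = 0.0
    hydro_buried = float(
        np.mean([(nl.chem_class == "hydrophobic") and nl.buried for nl in nls])
    )
    v = (
        list(chem_dist)
        + list(ss7_dist)
        + [float(np.mean(rsa_vals))] + rsa_bins
        + [frac_hb, mean_hb]
        + [float(np.mean(solv))] + solv_bins
        + [_entropy(chem_dist), _entropy(ss7_dist), _entropy(rsa_bins)]
        + [impurity]
        + [float(d_cen.mean()), float(d_cen.std())]
        + [float(cons.mean()), float(cons.min()), float(cons.max())]
        + _distribution(cons, config.CONSERVATION_BIN_EDGES)
        + [float(ncons.mean()), float(ncons.min()), float(ncons.max())]
        + [local, hydro_buried]
    )
    assert len(v) == GROUP_SIZES["node_stats"]
    return np.array(v)


def _neighborhood_impurity(g: ContactGraph, labels: Labels) -> float:
    """Mean over nodes of the number of graph neighbors with a different
    chemical class."""
    total = 0.0
    for x in g.nodes:
        cx = labels.chem_idx[x - 1]
        total += sum(1 for y in g.graph.neighbors(x) if labels.chem_idx[y - 1] != cx)
    return total / max(1, len(g))


def edge_label_statistics(g: ContactGraph, labels: Labels) -> np.ndarray:
    """12 statistics over the edge labels: link impurity, a 5-bin APC-MI
    distribution, cumulative and mean MI, and a 3-bin contact-potential
    distribution with its mean.  Graphs without edges yield zeros."""
    edges = sorted(g.edges)
    if not edges:
        out = np.zeros(GROUP_SIZES["edge_stats"])
        return out
    impure = float(
        np.mean([labels.chem_idx[a - 1] != labels.chem_idx[b - 1] for a, b in edges])
    )
    apcs = [labels.apc_mi[a - 1, b - 1] for a, b in edges]
    pots = [labels.potential(a, b) for a, b in edges]
    v = (
        [impure]
        + _distribution(apcs, config.MI_BIN_EDGES)
        + [float(np.sum(apcs))]
        + _distribution(pots, config.POTENTIAL_BIN_EDGES)
        + [float(np.mean(pots)), float(np.mean(apcs))]
    )
    assert len(v) == GROUP_SIZES["edge_stats"]
    return np.array(v)


def whole_protein_features(s: ProteinStructure, ss3: str) -> np.ndarray:
    """29 whole-chain inputs: amino acid composition (20), 3-state
    secondary structure composition (3) and a 6-class length one-hot."""
    comp = np.zeros(20)
    for r in s.residues:
        if r.aa in _AA_ORDER:
            comp[_AA_ORDER.index(r.aa)] += 1
    comp /= max(1, comp.sum())
    ss_comp = np.array([ss3.count(c) for c in config.SS3_CLASSES], dtype=float)
    ss_comp /= max(1, len(ss3))
    length_bin = _one_hot(_bin_index(s.L, tuple(e + 0.5 for e in config.LENGTH_CLASS_EDGES)), 6)
    out = np.concatenate([comp, ss_comp, length_bin])
    assert out.size == GROUP_SIZES["whole_protein"]
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureVector:
    """The fixed-schema encoding of one candidate contact in one decoy."""

    flat: np.ndarray
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.flat.size != TOTAL_INPUTS:
            raise ValueError(
                f"schema violation: {self.flat.size} inputs, expected {TOTAL_INPUTS}"
            )


def assemble_feature_vector(
    i: int,
    j: int,
    sng: ContactGraph,
    ing: ContactGraph,
    labels: Labels,
    ens: EnsembleContext,
    whole: np.ndarray,
    L: int,
) -> FeatureVector:
    """Concatenate all groups in the fixed order
    pairwise | SNG groups | ING groups | whole protein (238 inputs).
    Each graph-based group appears once per graph."""
    groups = {"pairwise": pairwise_features(i, j, labels, ens, L)}
    for tag, g in (("SNG", sng), ("ING", ing)):
        groups[f"topology_{tag}"] = topology_features(g)
        groups[f"spectrum_{tag}"] = spectrum_features(g)
        groups[f"single_node_{tag}"] = single_node_features(i, j, g, labels)
        groups[f"node_stats_{tag}"] = node_label_statistics(g, labels)
        groups[f"edge_stats_{tag}"] = edge_label_statistics(g, labels)
    groups["whole_protein"] = whole
    order = (
        ["pairwise"]
        + [f"{name}_SNG" for name in
           ("topology", "spectrum", "single_node", "node_stats", "edge_stats")]
        + [f"{name}_ING" for name in
           ("topology", "spectrum", "single_node", "node_stats", "edge_stats")]
        + ["whole_protein"]
    )
    flat = np.concatenate([groups[k] for k in order])
    return FeatureVector(flat=flat, groups=groups)


def feature_schema() -> list[str]:
    """Names of all 238 inputs in vector order."""
    names: list[str] = []
    for x in ("i", "j"):
        names += [f"pairwise.chem_{c}_{x}" for c in config.CHEM_CLASSES]
    for x in ("i", "j"):
        names += [f"pairwise.ss3_{c}_{x}" for c in config.SS3_CLASSES]
    names += ["pairwise.rsa_i", "pairwise.rsa_j",
              "pairwise.buried_i", "pairwise.buried_j",
              "pairwise.solvation_i", "pairwise.solvation_j",
              "pairwise.hydropathy_i", "pairwise.hydropathy_j",
              "pairwise.hbond_ij",
              "pairwise.hbond_count_i", "pairwise.hbond_count_j",
              "pairwise.separation"]
    names += [f"pairwise.separation_bin{k}" for k in range(4)]
    names += ["pairwise.nterm_dist_i", "pairwise.cterm_dist_i",
              "pairwise.nterm_dist_j", "pairwise.cterm_dist_j",
              "pairwise.contact_potential"]
    names += [f"pairwise.potential_bin{k}" for k in range(3)]
    names += ["pairwise.decoy_distance",
              "pairwise.ensemble_mean_distance", "pairwise.ensemble_sd_distance",
              "pairwise.mi", "pairwise.apc_mi"]
    topo = ["n_nodes", "n_edges", "avg_degree_centrality",
            "avg_closeness_centrality", "avg_betweenness_centrality",
            "radius", "diameter", "avg_eccentricity", "n_end_points",
            "avg_clustering"]
    spec = ["lambda1", "lambda2", "n_distinct_eigenvalues",
            "eigenvalue_sum", "graph_energy"]
    single = [f"{m}_{x}" for x in "ij"
              for m in ("degree", "closeness", "betweenness",
                        "conservation", "neigh_conservation")]
    nstats = (
        [f"chem_dist_{c}" for c in config.CHEM_CLASSES]
        + [f"ss7_dist_{c}" for c in config.SS7_CLASSES]
        + ["mean_rsa"] + [f"rsa_bin{k}" for k in range(3)]
        + ["frac_hbonded", "mean_hbond_count", "mean_solvation"]
        + [f"solvation_bin{k}" for k in range(4)]
        + ["chem_entropy", "ss7_entropy", "rsa_entropy",
           "neighborhood_impurity", "mean_centroid_dist", "sd_centroid_dist",
           "cons_mean", "cons_min", "cons_max"]
        + [f"cons_bin{k}" for k in range(4)]
        + ["ncons_mean", "ncons_min", "ncons_max",
           "frac_anchor_local", "frac_hydrophobic_buried"]
    )
    estats = (
        ["link_impurity"] + [f"apc_mi_bin{k}" for k in range(5)]
        + ["cumulative_mi"] + [f"potential_bin{k}" for k in range(3)]
        + ["mean_potential", "mean_mi"]
    )
    for tag in ("SNG", "ING"):
        names += [f"topology_{tag}.{n}" for n in topo]
        names += [f"spectrum_{tag}.{n}" for n in spec]
        names += [f"single_node_{tag}.{n}" for n in single]
        names += [f"node_stats_{tag}.{n}" for n in nstats]
        names += [f"edge_stats_{tag}.{n}" for n in estats]
    names += [f"whole_protein.aa_comp_{a}" for a in _AA_ORDER]
    names += [f"whole_protein.ss3_comp_{c}" for c in config.SS3_CLASSES]
    names += [f"whole_protein.length_class{k}" for k in range(6)]
    assert len(names) == TOTAL_INPUTS
    return names
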