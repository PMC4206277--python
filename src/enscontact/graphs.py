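"""Contact-graph constructions around a candidate contact.

Three graphs characterize the structural context of a contact (i, j) in a
decoy: the per-residue neighborhood graph N_i, the shared neighborhood
graph SNG(i, j) = induced graph on nodes(N_i) & nodes(N_j), and the
immediate neighborhood graph ING(i, j) on the anchors plus everything in
direct contact with either.  Edges are always the contacts induced among
the node set, so every graph is an induced subgraph of the full contact
graph of the decoy.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .structio import ContactMap

__all__ = [
    "NeighborhoodSpec",
    "ContactGraph",
    "full_contact_graph",
    "residue_neighborhood",
    "shared_neighborhood_graph",
    "immediate_neighborhood_graph",
]


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Sequence offsets seeding a residue neighborhood.

    The default window is i +/- 2.  For helical residues the window is
    replaced by i, i +/- 3, i +/- 4 — the positions with the same facing on
    the adjacent turns of an alpha helix (3.6 residues per turn).
    """

    default_offsets: tuple[int, ...] = (-2, -1, 0, 1, 2)
    helix_offsets: tuple[int, ...] = (-4, -3, 0, 3, 4)

    def seeds(self, i: int, L: int, is_helix: bool) -> set[int]:
        offs = self.helix_offsets if is_helix else self.default_offsets
        return {i + o for o in offs if 1 <= i + o <= L}


@dataclass
class ContactGraph:
    """An induced subgraph of a decoy's contact graph, optionally anchored
    at the candidate contact it contextualizes."""

    graph: nx.Graph
    anchor: tuple[int, int] | None = None

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {(min(a, b), max(a, b)) for a, b in self.graph.edges}

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def full_contact_graph(cm: ContactMap) -> nx.Graph:
    """The whole decoy as a graph: all residues, contact edges."""
    g = nx.Graph()
    g.add_nodes_from(range(1, cm.L + 1))
    g.add_edges_from(cm.pairs)
    return g


def _induced(cm: ContactMap, nodes: set[int],
             anchor: tuple[int, int] | None) -> ContactGraph:
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    g.add_edges_from((a, b) for (a, b) in cm.pairs if a in nodes and b in nodes)
    return ContactGraph(g, anchor)


def residue_neighborhood(
    cm: ContactMap,
    ss: str,
    i: int,
    spec: NeighborhoodSpec = NeighborhoodSpec(),
) -> ContactGraph:
    """N_i: sequence window around residue i plus all contacts of the window.

    ``ss`` is the per-residue 3-state secondary structure string; a helical
    residue i switches the seed window to the helix offsets.
    """
    if not 1 <= i <= cm.L:
        raise ValueError(f"residue index {i} outside 1..{cm.L}")
    seeds = spec.seeds(i, cm.L, ss[i - 1] == "H")
    nodes = set(seeds)
    for s in seeds:
        nodes |= cm.neighbors(s)
    return _induced(cm, nodes, None)


def shared_neighborhood_graph(
    cm: ContactMap,
    ss: str,
    i: int,
    j: int,
    spec: NeighborhoodSpec = NeighborhoodSpec(),
) -> ContactGraph:
    """SNG(i, j): intersection of the two residue neighborhoods.

    When (i, j) is a contact, i is a neighbor of j and vice versa, so both
    anchors are always contained in the intersection.
    """
    ni = residue_neighborhood(cm, ss, i, spec).nodes
    nj = residue_neighborhood(cm, ss, j, spec).nodes
    nodes = (ni & nj) | {i, j}
    return _induced(cm, nodes, (min(i, j), max(i, j)))


def immediate_neighborhood_graph(cm: ContactMap, i: int, j: int) -> ContactGraph:
    """ING(i, j): the anchors and every residue in contact with either."""
    nodes = {i, j} | cm.neighbors(i) | cm.neighbors(j)
    return _induced(cm, nodes, (min(i, j), max(i, j)))
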