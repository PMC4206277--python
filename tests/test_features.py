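import math

import networkx as nx
import numpy as np
import pytest

from enscontact import config
from enscontact.features import (GROUP_SIZES, assemble_feature_vector,
                                 assign_secondary_structure, build_labels,
                                 build_ensemble_context, compute_sasa,
                                 conservation_profile, detect_hbonds,
                                 edge_label_statistics, feature_schema,
                                 mutual_information_matrix,
                                 node_label_statistics, pairwise_features,
                                 single_node_features, spectrum_features,
                                 topology_features, whole_protein_features)
from enscontact.graphs import (ContactGraph, immediate_neighborhood_graph,
                               shared_neighborhood_graph)
from enscontact.structio import Msa, compute_contact_map
from enscontact.scoring import candidate_contacts

from conftest import make_chain


def cg(nodes, edges, anchor=None):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return ContactGraph(g, anchor)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_helical(self, helix_native):
        native, _, _ = helix_native
        _, ss3 = assign_secondary_structure(native)
        assert set(ss3[1:-1]) == {"H"}

    def test_ideal_strand_is_extended(self, strand_native):
        native, _, _ = strand_native
        _, ss3 = assign_secondary_structure(native)
        assert set(ss3[1:-1]) == {"E"}

    def test_two_residue_chain_is_coil(self):
        s = make_chain([{"CA": [0, 0, 0]}, {"CA": [3.8, 0, 0]}])
        assert assign_secondary_structure(s) == ("CC", "CC")


class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        s = make_chain([{"CA": [0.0, 0.0, 0.0]}])
        sasa, _, atom_sasa = compute_sasa(s)
        r = config.VDW_RADII["C"] + config.SASA_PROBE_RADIUS
        expected = 4 * math.pi * r ** 2
        assert atom_sasa[0] == pytest.approx(expected, rel=0.02)

    def test_enclosed_atom_has_zero_sasa(self):
        # central atom caged by 26 overlapping atoms on a 2 A grid shell
        shell = [
            {"CA": [2.0 * x, 2.0 * y, 2.0 * z]}
            for x in (-1, 0, 1) for y in (-1, 0, 1) for z in (-1, 0, 1)
        ]
        s = make_chain(shell)
        _, _, atom_sasa = compute_sasa(s)
        center = 13  # the (0,0,0) atom
        assert atom_sasa[center] == pytest.approx(0.0, abs=1e-9)

    def test_point_count_convergence(self, helix_native):
        native, _, _ = helix_native
        a, _, _ = compute_sasa(native, n_points=92)
        b, _, _ = compute_sasa(native, n_points=184)
        assert abs(a.sum() - b.sum()) / b.sum() < 0.02
        mask = b > 10.0
        assert np.max(np.abs(a[mask] - b[mask]) / b[mask]) < 0.10


class TestHbonds:
    @pytest.mark.parametrize("sep,expected", [(4, True), (1, False)])
    def test_distance_and_separation_rules(self, sep, expected):
        coords = [{"N": [50.0 * k, 0, 0], "O": [50.0 * k + 1, 0, 0],
                   "CA": [50.0 * k, 1, 0]} for k in range(6)]
        # move O of residue 0 within 3.2 A of N of residue `sep`
        coords[0]["O"] = [50.0 * sep - 3.2, 0.0, 0.0]
        s = make_chain(coords)
        bonds = detect_hbonds(s)
        assert ((sep + 1, 1) in bonds) is expected

    def test_helix_ladder(self, helix_native):
        native, _, _ = helix_native
        bonds = detect_hbonds(native)
        ladder = [(i + 4, i) for i in range(1, native.L - 4)]
        present = sum(1 for b in ladder if b in bonds)
        assert present >= len(ladder) * 0.8


class TestConservation:
    def test_conserved_column_is_one(self):
        m = Msa(["A" * 3] * 50)
        cons, _ = conservation_profile(m)
        assert cons == pytest.approx([1.0, 1.0, 1.0])

    def test_uniform_column_tends_to_zero(self):
        letters = "ACDEFGHIKLMNPQRSTVWY"
        rows = [letters[k % 20] for k in range(400)]
        m = Msa([r for r in rows])
        cons, _ = conservation_profile(m)
        assert cons[0] < 0.05

    def test_depth_one_alignment_is_fully_conserved(self):
        cons, neigh = conservation_profile(Msa(["ACDEF"]))
        assert np.allclose(cons, 1.0) and np.allclose(neigh, 1.0)


class TestMutualInformation:
    def test_coupled_binary_columns_approach_log2(self):
        rng = np.random.default_rng(0)
        rows = ["AC" if rng.random() < 0.5 else "CA" for _ in range(3000)]
        mi, _ = mutual_information_matrix(Msa(rows))
        assert mi[0, 1] == pytest.approx(math.log(2), rel=0.05)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        rows = [
            "".join(rng.choice(list("ACDE"), 2)) for _ in range(3000)
        ]
        mi, _ = mutual_information_matrix(Msa(rows))
        # residual floor comes from the pseudocount mixture, not coupling
        assert mi[0, 1] < 0.05

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        rows = ["".join(rng.choice(list("ACDEFG"), 5)) for _ in range(100)]
        mi, apc = mutual_information_matrix(Msa(rows))
        assert np.allclose(mi, mi.T) and np.allclose(apc, apc.T)

    def test_depth_one_all_zero(self):
        mi, apc = mutual_information_matrix(Msa(["ACDEF"]))
        assert not mi.any() and not apc.any()


@pytest.fixture(scope="module")
def labeled_decoy(mixed_native):
    native, cm, seq = mixed_native
    labels = build_labels(native)
    ens = build_ensemble_context([native])
    return native, cm, labels, ens


class TestPairwise:
    def test_length_and_one_hot_blocks(self, labeled_decoy):
        native, cm, labels, ens = labeled_decoy
        i, j = candidate_contacts(cm)[0]
        v = pairwise_features(i, j, labels, ens, native.L)
        assert v.size == GROUP_SIZES["pairwise"]
        assert v[0:7].sum() == 1.0 and v[7:14].sum() == 1.0  # chem one-hots
        assert v[14:17].sum() == 1.0 and v[17:20].sum() == 1.0  # ss3
        sep_block = v[32:36]
        assert sep_block.sum() == 1.0

    def test_swap_permutes_residue_blocks(self, labeled_decoy):
        native, cm, labels, ens = labeled_decoy
        i, j = candidate_contacts(cm)[0]
        a = pairwise_features(i, j, labels, ens, native.L)
        b = pairwise_features(j, i, labels, ens, native.L)
        # chem blocks swap
        assert np.array_equal(a[0:7], b[7:14]) and np.array_equal(a[7:14], b[0:7])
        # symmetric tail (potential, distances, mi) unchanged
        assert np.allclose(a[-8:], b[-8:])


class TestTopology:
    def test_path_worked_values(self):
        g = cg([1, 2, 3], [(1, 2), (2, 3)])
        v = topology_features(g)
        expected = [3, 2, 2 / 3, 7 / 9, 1 / 3, 1, 2, 5 / 3, 2, 0]
        assert np.allclose(v, expected, atol=1e-9)

    def test_triangle(self):
        g = cg([1, 2, 3], [(1, 2), (2, 3), (1, 3)])
        v = topology_features(g)
        assert v[9] == 1.0 and v[8] == 0.0 and v[5] == v[6] == 1.0

    def test_single_edge(self):
        v = topology_features(cg([1, 2], [(1, 2)]))
        assert v[8] == 2.0 and v[2] == 1.0

    def test_single_node(self):
        v = topology_features(cg([5], []))
        assert v[0] == 1.0 and not v[1:].any()


class TestSpectrum:
    def test_path_spectrum(self):
        v = spectrum_features(cg([1, 2, 3], [(1, 2), (2, 3)]))
        assert v[0] == pytest.approx(math.sqrt(2), abs=1e-9)
        assert v[1] == pytest.approx(0.0, abs=1e-9)
        assert v[2] == 3
        assert v[3] == pytest.approx(0.0, abs=1e-9)
        assert v[4] == pytest.approx(2 * math.sqrt(2), abs=1e-9)

    def test_trace_zero_and_energy_bound(self):
        rng = np.random.default_rng(3)
        import itertools
        for _ in range(20):
            n = int(rng.integers(2, 8))
            nodes = list(range(1, n + 1))
            edges = [e for e in itertools.combinations(nodes, 2)
                     if rng.random() < 0.4]
            v = spectrum_features(cg(nodes, edges))
            assert v[3] == pytest.approx(0.0, abs=1e-9)
            if edges:
                assert v[4] >= 2 * v[0] - 1e-9
            assert v[2] <= n

    def test_single_node(self):
        assert np.array_equal(spectrum_features(cg([1], [])),
                              [0, 0, 1, 0, 0])


class TestSingleNode:
    def test_length_and_symmetry(self, labeled_decoy):
        native, cm, labels, ens = labeled_decoy
        i, j = candidate_contacts(cm)[0]
        g = immediate_neighborhood_graph(cm, i, j)
        a = single_node_features(i, j, g, labels)
        assert a.size == GROUP_SIZES["single_node"]
        b = single_node_features(j, i, g, labels)
        assert np.array_equal(a[:5], b[5:]) and np.array_equal(a[5:], b[:5])

    def test_anchor_absent_is_fatal(self, labeled_decoy):
        _, cm, labels, _ = labeled_decoy
        g = cg([1, 2], [(1, 2)])
        with pytest.raises(ValueError, match="anchors"):
            single_node_features(1, 55, g, labels)


class TestNodeStats:
    def test_length_and_distribution_sums(self, labeled_decoy):
        native, cm, labels, _ = labeled_decoy
        i, j = candidate_contacts(cm)[0]
        g = shared_neighborhood_graph(cm, labels.ss3, i, j)
        v = node_label_statistics(g, labels)
        assert v.size == GROUP_SIZES["node_stats"]
        assert v[0:7].sum() == pytest.approx(1.0)   # chem distribution
        assert v[7:14].sum() == pytest.approx(1.0)  # ss7 distribution
        assert v[15:18].sum() == pytest.approx(1.0)  # rsa bins
        # entropies bounded by log of class count
        assert 0 <= v[25] <= math.log(7) + 1e-12
        assert 0 <= v[26] <= math.log(7) + 1e-12

    def test_all_hydrophobic_graph(self, labeled_decoy):
        native, cm, labels, _ = labeled_decoy
        hydro = [k + 1 for k in range(native.L) if labels.chem_idx[k] == 0]
        g = cg(hydro[:3], [])
        v = node_label_statistics(g, labels)
        assert v[0] == 1.0 and v[1:7].sum() == 0.0
        assert v[25] == 0.0  # chem entropy

    def test_single_node_centroid_distance_zero(self, labeled_decoy):
        _, _, labels, _ = labeled_decoy
        v = node_label_statistics(cg([4], []), labels)
        assert v[29] == 0.0 and v[30] == 0.0


class TestEdgeStats:
    def test_no_edges_all_zero(self, labeled_decoy):
        _, _, labels, _ = labeled_decoy
        v = edge_label_statistics(cg([1, 5], []), labels)
        assert v.size == GROUP_SIZES["edge_stats"] and not v.any()

    def test_distribution_sums_and_impurity_range(self, labeled_decoy):
        native, cm, labels, _ = labeled_decoy
        i, j = candidate_contacts(cm)[0]
        g = immediate_neighborhood_graph(cm, i, j)
        v = edge_label_statistics(g, labels)
        if g.edges:
            assert v[1:6].sum() == pytest.approx(1.0)  # MI bins
            assert v[7:10].sum() == pytest.approx(1.0)  # potential bins
            assert 0.0 <= v[0] <= 1.0


class TestWholeProtein:
    def test_composition_sums(self, mixed_native):
        native, _, _ = mixed_native
        _, ss3 = assign_secondary_structure(native)
        v = whole_protein_features(native, ss3)
        assert v.size == GROUP_SIZES["whole_protein"]
        assert v[:20].sum() == pytest.approx(1.0)
        assert v[23:].sum() == 1.0

    @pytest.mark.parametrize("L,bin_index", [(50, 0), (51, 1), (120, 2),
                                             (200, 3), (300, 4), (500, 5)])
    def test_length_class_bins(self, L, bin_index):
        s = make_chain([{"CA": [3.8 * k, 0, 0]} for k in range(L)],
                       "A" * L)
        v = whole_protein_features(s, "C" * L)
        assert v[23 + bin_index] == 1.0 and v[23:].sum() == 1.0


class TestAssembly:
    def test_total_length_and_determinism(self, labeled_decoy):
        native, cm, labels, ens = labeled_decoy
        i, j = candidate_contacts(cm)[0]
        sng = shared_neighborhood_graph(cm, labels.ss3, i, j)
        ing = immediate_neighborhood_graph(cm, i, j)
        from enscontact.features import whole_protein_features
        whole = whole_protein_features(native, labels.ss3)
        fv1 = assemble_feature_vector(i, j, sng, ing, labels, ens, whole,
                                      native.L)
        fv2 = assemble_feature_vector(i, j, sng, ing, labels, ens, whole,
                                      native.L)
        assert fv1.flat.size == 238
        assert np.array_equal(fv1.flat, fv2.flat)

    def test_rigid_motion_invariance(self, mixed_native):
        native, cm, _ = mixed_native
        # rotate + translate all coordinates
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = np.array([10.0, -5.0, 3.0])
        moved = make_chain(
            [{n: q @ x + t for n, x in r.atoms.items()}
             for r in native.residues],
            native.sequence,
        )
        la = build_labels(native)
        lb = build_labels(moved)
        ea = build_ensemble_context([native])
        eb = build_ensemble_context([moved])
        cma = compute_contact_map(native)
        cmb = compute_contact_map(moved)
        assert cma.pairs == cmb.pairs
        i, j = candidate_contacts(cma)[0]
        wa = whole_protein_features(native, la.ss3)
        wb = whole_protein_features(moved, lb.ss3)
        fva = assemble_feature_vector(
            i, j, shared_neighborhood_graph(cma, la.ss3, i, j),
            immediate_neighborhood_graph(cma, i, j), la, ea, wa, native.L)
        fvb = assemble_feature_vector(
            i, j, shared_neighborhood_graph(cmb, lb.ss3, i, j),
            immediate_neighborhood_graph(cmb, i, j), lb, eb, wb, moved.L)
        # accessibility-derived inputs are estimated by finite sphere
        # sampling with fixed point directions, so they are only
        # approximately rotation invariant; everything else is exact
        names = feature_schema()
        sampled = np.array([
            any(tag in n for tag in ("rsa", "buried", "solvation"))
            for n in names
        ])
        np.testing.assert_allclose(fva.flat[~sampled], fvb.flat[~sampled],
                                   atol=1e-8)
        np.testing.assert_allclose(fva.flat[sampled], fvb.flat[sampled],
                                   atol=0.25)

    def test_schema_names_cover_all_inputs(self):
        names = feature_schema()
        assert len(names) == 238 and len(set(names)) == 238
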