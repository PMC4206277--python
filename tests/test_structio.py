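import numpy as np
import pytest

from enscontact.structio import (ContactMap, DecoyEnsemble, compute_contact_map,
                                 contact_atom, read_energy_table,
                                 read_evolutionary_scores, read_msa, read_rr,
                                 read_structure, select_low_energy,
                                 write_rr, write_structure)

from conftest import make_chain

PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CB  ALA A   1       2.000  -1.000   1.000  1.00  0.00           C
ATOM      5  N   GLY A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       4.200   2.600   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.600   2.000   0.000  1.00  0.00           C
ATOM      8  N   SER A   3       6.600   2.900   0.000  1.00  0.00           N
ATOM      9  CA  SER A   3       8.000   2.500   0.000  1.00  0.00           C
ATOM     10  C   SER A   3       9.000   3.600   0.000  1.00  0.00           C
TER
END
"""

PDB_ALTLOC = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C
TER
END
"""

PDB_MSE = """\
HETATM    1  N   MSE A   1       0.000   0.000   0.000  1.00  0.00           N
HETATM    2  CA  MSE A   1       1.458   0.000   0.000  1.00  0.00           C
TER
END
"""


class TestReadStructure:
    def test_minimal_three_residue_parse(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_3RES)
        s = read_structure(path)
        assert s.L == 3
        assert s.sequence == "AGS"
        assert s.residues[0].seq_index == 1

    def test_altloc_resolves_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(PDB_ALTLOC)
        s = read_structure(path)
        assert s.residues[0].atoms["CA"][0] == pytest.approx(1.0)

    def test_selenomethionine_kept_as_met(self, tmp_path):
        path = tmp_path / "mse.pdb"
        path.write_text(PDB_MSE)
        s = read_structure(path)
        assert s.sequence == "M"

    def test_missing_chain_is_fatal(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_3RES)
        with pytest.raises(ValueError, match="chain"):
            read_structure(path, chain="Z")

    def test_write_read_round_trip(self, tmp_path, helix_native):
        native, _, _ = helix_native
        path = tmp_path / "helix.pdb"
        write_structure(native, path)
        back = read_structure(path)
        assert back.L == native.L
        assert back.sequence == native.sequence
        np.testing.assert_allclose(back.coords("CA"), native.coords("CA"),
                                   atol=1e-3)


class TestContactAtom:
    def test_cb_when_present(self):
        s = make_chain([{"CA": [0, 0, 0], "CB": [1, 0, 0]}], "A")
        assert contact_atom(s.residues[0])[0] == 1.0

    def test_glycine_uses_ca(self):
        s = make_chain([{"CA": [0, 0, 0], "CB": [9, 9, 9]}], "G")
        np.testing.assert_array_equal(contact_atom(s.residues[0]), [0, 0, 0])

    def test_missing_cb_falls_back_to_ca_with_warning(self):
        s = make_chain([{"CA": [2, 0, 0]}], "A")
        with pytest.warns(UserWarning, match="missing CB"):
            np.testing.assert_array_equal(contact_atom(s.residues[0]), [2, 0, 0])


class TestContactMap:
    def test_threshold_inclusion_and_exclusion(self):
        for d, expect in ((7.9, True), (8.1, False)):
            s = make_chain([{"CA": [0, 0, 0]}, {"CA": [d, 0, 0]}], "GG")
            cm = compute_contact_map(s)
            assert ((1, 2) in cm) is expect

    def test_symmetry_and_idempotence(self, mixed_native):
        native, cm, _ = mixed_native
        assert all(i < j for i, j in cm.pairs)
        assert all((j, i) in cm for i, j in cm.pairs)
        assert compute_contact_map(native).pairs == cm.pairs

    def test_min_separation_excludes_close_pairs(self, mixed_native):
        native, _, _ = mixed_native
        cm = compute_contact_map(native, min_separation=12)
        assert all(j - i >= 12 for i, j in cm.pairs)


class TestMsa:
    def test_single_sequence_fasta(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">q\nACDEF\n")
        m = read_msa(p)
        assert m.depth == 1 and m.query == "ACDEF"

    def test_a3m_lowercase_insertions_removed(self, tmp_path):
        p = tmp_path / "aln.a3m"
        p.write_text(">q\nACDEF\n>h\nAcaCDEF\n"[:100])
        # second row has lowercase insertions; after removal both rows
        # must match the query length
        p.write_text(">q\nACDEF\n>h\nAcaCD-F\n")
        m = read_msa(p)
        assert m.depth == 2
        assert all(len(r) == 5 for r in m.sequences)

    def test_ragged_alignment_is_fatal(self, tmp_path):
        p = tmp_path / "bad.a3m"
        p.write_text(">q\nACDEF\n>h\nACD\n")
        with pytest.raises(ValueError, match="ragged"):
            read_msa(p)

    def test_synthetic_depth(self, tmp_path):
        rows = "".join(f">s{k}\nAC\n" for k in range(100))
        p = tmp_path / "deep.fasta"
        p.write_text(rows)
        assert read_msa(p).depth == 100


class TestEvolutionaryScores:
    def test_parse_and_default_zero(self, tmp_path):
        p = tmp_path / "evo.tsv"
        p.write_text("3\t10\t1.25\n")
        g = read_evolutionary_scores(p)
        assert g.get(3, 10) == 1.25
        assert g.get(10, 3) == 1.25
        assert g.get(1, 2) == 0.0

    def test_duplicate_last_wins(self, tmp_path):
        p = tmp_path / "evo.tsv"
        p.write_text("10\t3\t1.0\n3\t10\t2.0\n")
        with pytest.warns(UserWarning, match="duplicate"):
            g = read_evolutionary_scores(p)
        assert g.get(3, 10) == 2.0

    def test_out_of_range_fatal_when_length_known(self, tmp_path):
        p = tmp_path / "evo.tsv"
        p.write_text("3\t99\t1.0\n")
        with pytest.raises(ValueError, match="out of range"):
            read_evolutionary_scores(p, L=50)

    def test_rescaled_to_unit_interval(self, tmp_path):
        p = tmp_path / "evo.tsv"
        p.write_text("1\t20\t-3.0\n2\t30\t5.0\n3\t40\t1.0\n")
        r = read_evolutionary_scores(p).rescaled()
        vals = sorted(r.scores.values())
        assert vals[0] == 0.0 and vals[-1] == 1.0


class TestEnergyTable:
    def test_parse(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("".join(f"d{k}\t{k * 0.1}\n" for k in range(1000)))
        assert len(read_energy_table(p)) == 1000

    def test_duplicate_id_fatal(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("d0\t1.0\nd0\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_energy_table(p)

    def test_decoy_without_energy_fatal(self):
        s = make_chain([{"CA": [0, 0, 0]}])
        s.id = "orphan"
        with pytest.raises(ValueError, match="without energy"):
            DecoyEnsemble([s], {})


def _toy_ensemble(n, energies=None):
    decoys = []
    emap = {}
    for k in range(n):
        s = make_chain([{"CA": [0, 0, 0]}])
        s.id = f"d{k:04d}"
        decoys.append(s)
        emap[s.id] = energies[k] if energies is not None else float(k)
    return DecoyEnsemble(decoys, emap)


class TestSelectLowEnergy:
    @pytest.mark.parametrize("n,fraction,expected", [(1000, 0.02, 20),
                                                     (200, 0.03, 6)])
    def test_ceiling_counts(self, n, fraction, expected):
        sel = select_low_energy(_toy_ensemble(n), fraction)
        assert len(sel.selected) == expected

    def test_equal_energies_tie_by_id(self):
        sel = select_low_energy(_toy_ensemble(10, [1.0] * 10), 0.3)
        assert [d.id for d in sel.selected] == ["d0000", "d0001", "d0002"]

    def test_full_fraction_returns_all_and_nesting(self):
        ens = _toy_ensemble(50)
        assert len(select_low_energy(ens, 1.0).selected) == 50
        small = {d.id for d in select_low_energy(ens, 0.1).selected}
        big = {d.id for d in select_low_energy(ens, 0.5).selected}
        assert small <= big

    def test_empty_ensemble_fatal(self):
        with pytest.raises(ValueError):
            select_low_energy(DecoyEnsemble([], {}), 0.5)


class TestRR:
    def test_round_trip_and_monotone_scores(self, tmp_path):
        ranked = [(3, 40, 0.9), (5, 30, 0.5), (1, 25, 0.1)]
        path = tmp_path / "pred.rr"
        write_rr(ranked, path, sequence="A" * 40)
        back = read_rr(path)
        assert [(i, j) for i, j, _ in back] == [(3, 40), (5, 30), (1, 25)]
        scores = [s for _, _, s in back]
        assert scores == sorted(scores, reverse=True)
        for (i, j, s), (i2, j2, s2) in zip(ranked, back):
            assert (i, j) == (i2, j2) and s == pytest.approx(s2, abs=1e-6)

    def test_upper_distance_column_is_contact_threshold(self, tmp_path):
        path = tmp_path / "pred.rr"
        write_rr([(1, 20, 0.7)], path)
        row = [l for l in path.read_text().splitlines() if l[0].isdigit()][0]
        assert row.split()[2:4] == ["0", "8"]
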