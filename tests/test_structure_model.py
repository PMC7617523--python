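"""Data model and PDB round-trip behaviour."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ppi_missense.errors import ChainNotFoundError, EmptyStructureError, InputError
from ppi_missense.structure_model import (
    Atom,
    Residue,
    extract_monomer,
    min_heavy_atom_distance,
    parse_structure,
    write_structure,
)

ALTLOC_PDB = """\
ATOM      1  N   SER A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  SER A   1      10.500   5.000  -5.800  1.00  0.00           C
ATOM      3  C   SER A   1       9.500   5.500  -4.800  1.00  0.00           C
ATOM      4  O   SER A   1       9.800   6.400  -4.000  1.00  0.00           O
ATOM      5  CB ASER A   1      11.500   4.200  -5.000  0.60  0.00           C
ATOM      6  CB BSER A   1      11.400   4.100  -5.100  0.40  0.00           C
ATOM      7  OG ASER A   1      12.500   3.700  -5.800  0.60  0.00           O
ATOM      8  OG BSER A   1      12.400   3.600  -5.900  0.40  0.00           O
ATOM      9  H   SER A   1      11.000   7.000  -6.000  1.00  0.00           H
TER
END
"""


def _round_trip(structure, tmp_path, name="rt.pdb"):
    path = tmp_path / name
    write_structure(structure, path)
    return parse_structure(path)


class TestParsing:
    def test_fixture_dimer_inventory(self, salt_bridge_dimer, tmp_path):
        s = _round_trip(salt_bridge_dimer, tmp_path)
        assert s.n_chains == 2
        assert [len(s.chains[c]) for c in s.chain_ids] == [7, 7]

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB)
        s = parse_structure(path)
        res = s.get_residue(("A", 1, ""))
        names = [a.name for a in res.atoms]
        assert names.count("CB") == 1 and names.count("OG") == 1
        # occupancy 0.60 conformer retained
        assert np.allclose(res.atom("CB").coord, [11.5, 4.2, -5.0])
        # hydrogens dropped on load
        assert "H" not in names

    def test_unreadable_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            parse_structure(tmp_path / "missing.pdb")

    def test_no_protein_residues_is_empty_error(self, tmp_path):
        path = tmp_path / "water.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\nEND\n"
        )
        with pytest.raises(EmptyStructureError):
            parse_structure(path)


class TestRoundTrip:
    def test_coordinates_preserved_to_3dp(self, salt_bridge_dimer, tmp_path):
        s = _round_trip(salt_bridge_dimer, tmp_path)
        for res in salt_bridge_dimer.residues():
            back = s.get_residue(res.key)
            assert back.res_name == res.res_name
            for a in res.atoms:
                assert np.allclose(back.atom(a.name).coord, a.coord, atol=5e-4)

    def test_insertion_codes_preserved(self, tmp_path):
        res = Residue("A", 10, "B", "GLY", [
            Atom("N", "N", np.array([0.0, 0.0, 0.0]), 1.55),
            Atom("CA", "C", np.array([1.46, 0.0, 0.0]), 1.70),
            Atom("C", "C", np.array([2.0, 1.4, 0.0]), 1.70),
            Atom("O", "O", np.array([1.5, 2.4, 0.0]), 1.52),
        ])
        from ppi_missense.structure_model import Structure
        s = Structure("icode", {"A": [res]})
        back = _round_trip(s, tmp_path, "icode.pdb")
        assert back.get_residue(("A", 10, "B")).res_name == "GLY"


class TestMonomerExtraction:
    def test_single_chain_with_identical_coordinates(self, salt_bridge_dimer):
        mono = extract_monomer(salt_bridge_dimer, "A")
        assert mono.chain_ids == ["A"]
        for res in salt_bridge_dimer.chains["A"]:
            np.testing.assert_array_equal(
                mono.get_residue(res.key).coords(), res.coords()
            )

    def test_idempotent(self, salt_bridge_dimer):
        once = extract_monomer(salt_bridge_dimer, "A")
        twice = extract_monomer(once, "A")
        for r1, r2 in zip(once.chains["A"], twice.chains["A"]):
            np.testing.assert_array_equal(r1.coords(), r2.coords())

    def test_missing_chain_raises(self, salt_bridge_dimer):
        with pytest.raises(ChainNotFoundError):
            extract_monomer(salt_bridge_dimer, "Z")


class TestMinHeavyAtomDistance:
    def test_self_distance_zero(self, salt_bridge_dimer):
        res = salt_bridge_dimer.chains["A"][0]
        assert min_heavy_atom_distance(res, res) == 0.0

    def test_three_four_five_triangle(self):
        r1 = Residue("A", 1, "", "GLY", [Atom("CA", "C", np.zeros(3), 1.7)])
        r2 = Residue("B", 1, "", "GLY", [Atom("CA", "C", np.array([3.0, 4.0, 0.0]), 1.7)])
        assert min_heavy_atom_distance(r1, r2) == pytest.approx(5.0)

    def test_matches_brute_force_scan(self, salt_bridge_dimer):
        target = salt_bridge_dimer.get_residue(("A", 4, ""))
        fast = {
            res.key
            for res in salt_bridge_dimer.residues()
            if res.key != target.key and min_heavy_atom_distance(target, res) < 5.0
        }
        brute = set()
        for res in salt_bridge_dimer.residues():
            if res.key == target.key:
                continue
            d = cdist(target.coords(), res.coords()).min()
            if d < 5.0:
                brute.add(res.key)
        assert fast == brute

    def test_symmetry(self, salt_bridge_dimer):
        a = salt_bridge_dimer.get_residue(("A", 4, ""))
        b = salt_bridge_dimer.get_residue(("B", 4, ""))
        assert min_heavy_atom_distance(a, b) == min_heavy_atom_distance(b, a)
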