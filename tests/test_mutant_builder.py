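"""Repack shell selection and mutant construction contracts."""

import numpy as np
import pytest

from ppi_missense.chem import SIDECHAIN_ATOMS
from ppi_missense.errors import VariantMismatchError
from ppi_missense.fixtures import Contact, FixtureSpec, make_dimer
from ppi_missense.geometry import bond_angle
from ppi_missense.mutant_builder import (
    RepackParams,
    VariantSpec,
    build_mutant,
    select_repack_shell,
)
from ppi_missense.structure_model import min_heavy_atom_distance


class TestRepackShell:
    def test_isolated_site_is_alone(self, separated_dimer):
        # chain B is 50 Å away; shell of a chain-A site stays within A
        shell = select_repack_shell(separated_dimer, ("A", 4, ""), 5.0)
        assert ("A", 4, "") in shell
        assert all(k[0] == "A" for k in shell)

    @pytest.mark.parametrize("distance, included", [(4.2, True), (5.3, False)])
    def test_partner_inclusion_is_distance_gated(self, distance, included):
        s = make_dimer(FixtureSpec(
            engineered_contacts=[Contact(4, 4, "salt_bridge", distance)],
        ))
        shell = select_repack_shell(s, ("A", 4, ""), 5.0)
        assert (("B", 4, "") in shell) == included

    def test_matches_brute_force(self, salt_bridge_dimer):
        site = ("A", 4, "")
        site_res = salt_bridge_dimer.get_residue(site)
        brute = {site} | {
            r.key for r in salt_bridge_dimer.residues()
            if r.key != site and min_heavy_atom_distance(site_res, r) < 5.0
        }
        assert set(select_repack_shell(salt_bridge_dimer, site, 5.0)) == brute


class TestBuildMutant:
    def test_backbone_bit_identical(self, salt_bridge_dimer):
        mut = build_mutant(salt_bridge_dimer, VariantSpec("A", 4, "", "LYS", "ALA"))
        for res in salt_bridge_dimer.residues():
            got = mut.structure.get_residue(res.key)
            for a in res.backbone:
                np.testing.assert_array_equal(got.atom(a.name).coord, a.coord)

    def test_wild_type_mismatch_is_hard_error(self, salt_bridge_dimer):
        with pytest.raises(VariantMismatchError):
            build_mutant(salt_bridge_dimer, VariantSpec("A", 4, "", "GLU", "ALA"))

    def test_mutant_site_has_canonical_atom_inventory(self, salt_bridge_dimer):
        mut = build_mutant(salt_bridge_dimer, VariantSpec("A", 4, "", "LYS", "TRP"))
        site = mut.structure.get_residue(("A", 4, ""))
        assert site.res_name == "TRP"
        got = {a.name for a in site.sidechain}
        assert got == set(SIDECHAIN_ATOMS["TRP"])

    def test_gly_to_ala_adds_single_ideal_cb(self):
        s = make_dimer(FixtureSpec(
            sequence_a=["ALA", "ALA", "ALA", "GLY", "ALA", "ALA", "ALA"],
            engineered_contacts=[],
            separation=50.0,
        ))
        mut = build_mutant(s, VariantSpec("A", 4, "", "GLY", "ALA"))
        site = mut.structure.get_residue(("A", 4, ""))
        assert [a.name for a in site.sidechain] == ["CB"]
        cb = site.atom("CB").coord
        n_ca_cb = bond_angle(site.atom("N").coord, site.atom("CA").coord, cb)
        c_ca_cb = bond_angle(site.atom("C").coord, site.atom("CA").coord, cb)
        assert abs(n_ca_cb - 110.1) < 2.0
        assert abs(c_ca_cb - 109.4) < 2.0

    def test_gly_target_strips_sidechain(self, salt_bridge_dimer):
        mut = build_mutant(salt_bridge_dimer, VariantSpec("A", 4, "", "LYS", "GLY"))
        assert mut.structure.get_residue(("A", 4, "")).sidechain == []

    def test_self_mutation_reproduces_wild_type_pack(self, salt_bridge_dimer):
        """Minimal-perturbation repack keeps clash-free wild-type side
        chains, so a self-mutation is coordinate-identical to the input."""
        mut = build_mutant(salt_bridge_dimer, VariantSpec("A", 4, "", "LYS", "LYS"))
        for res in salt_bridge_dimer.residues():
            got = mut.structure.get_residue(res.key)
            np.testing.assert_array_equal(got.coords(), res.coords())

    def test_determinism_bit_identical(self, salt_bridge_dimer):
        v = VariantSpec("A", 4, "", "LYS", "ARG")
        m1 = build_mutant(salt_bridge_dimer, v)
        m2 = build_mutant(salt_bridge_dimer, v)
        for r1 in m1.structure.residues():
            r2 = m2.structure.get_residue(r1.key)
            np.testing.assert_array_equal(r1.coords(), r2.coords())
        assert m1.repacked_residues == m2.repacked_residues
        assert m1.packing_score == m2.packing_score

    def test_non_shell_sidechains_untouched(self, salt_bridge_dimer):
        v = VariantSpec("A", 4, "", "LYS", "SER")
        mut = build_mutant(salt_bridge_dimer, v)
        shell = set(mut.repacked_residues)
        for res in salt_bridge_dimer.residues():
            if res.key in shell:
                continue
            got = mut.structure.get_residue(res.key)
            np.testing.assert_array_equal(got.coords(), res.coords())

    def test_repacked_equals_shell_selection(self, salt_bridge_dimer):
        v = VariantSpec("A", 4, "", "LYS", "ARG")
        mut = build_mutant(salt_bridge_dimer, v, RepackParams())
        assert mut.repacked_residues == select_repack_shell(
            salt_bridge_dimer, v.site, 5.0)
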