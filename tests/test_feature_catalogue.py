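"""Interchain bond / clash / bend / cavity detectors and feature gating."""

import numpy as np
import pytest

from ppi_missense.feature_catalogue import (
    CORE_SUPPORT_ONLY,
    BondCriteria,
    FeatureID,
    assign_bend_state,
    detect_interchain_bonds,
    detect_interchain_clashes,
    evaluate_features,
)
from ppi_missense.fixtures import Contact, FixtureSpec, build_chain, make_dimer
from ppi_missense.interface_map import map_interface
from ppi_missense.mutant_builder import VariantSpec, build_mutant
from ppi_missense.structure_model import Structure


class TestBondDetection:
    def test_engineered_salt_bridge_found(self, salt_bridge_dimer):
        bonds = detect_interchain_bonds(salt_bridge_dimer)
        bridges = [b for b in bonds if b.kind == "salt_bridge"]
        assert any(
            {b.atom1, b.atom2} == {"NZ", "OE1"} and b.distance == pytest.approx(3.0, abs=0.01)
            for b in bridges
        )

    def test_beyond_effective_cutoff_not_found(self):
        s = make_dimer(FixtureSpec(engineered_contacts=[Contact(4, 4, "salt_bridge", 5.5)]))
        bonds = detect_interchain_bonds(s)
        assert not [b for b in bonds if b.kind == "salt_bridge"]

    @pytest.mark.parametrize("d, detected", [(4.99, True), (5.01, False)])
    def test_detection_flips_exactly_at_effective_cutoff(self, d, detected):
        s = make_dimer(FixtureSpec(engineered_contacts=[Contact(4, 4, "salt_bridge", d)]))
        bridges = [b for b in detect_interchain_bonds(s)
                   if b.kind == "salt_bridge" and {b.atom1, b.atom2} == {"NZ", "OE1"}]
        assert bool(bridges) == detected

    def test_disulfide_at_canonical_length(self):
        s = make_dimer(FixtureSpec(engineered_contacts=[Contact(4, 4, "disulfide", 2.05)]))
        bonds = [b for b in detect_interchain_bonds(s) if b.kind == "disulfide"]
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.05, abs=0.01)

    def test_salt_bridge_pairs_not_double_counted_as_hbonds(self, salt_bridge_dimer):
        bonds = detect_interchain_bonds(salt_bridge_dimer)
        charged_pairs = {("NZ", "OE1"), ("NZ", "OE2"), ("OE1", "NZ"), ("OE2", "NZ")}
        for b in bonds:
            if b.kind == "hbond":
                assert (b.atom1, b.atom2) not in charged_pairs

    def test_symmetric_in_chain_order(self, salt_bridge_dimer):
        reordered = Structure(
            "r", {cid: salt_bridge_dimer.chains[cid]
                  for cid in reversed(salt_bridge_dimer.chain_ids)},
        )
        a = {(b.kind, b.res1, b.res2, b.atom1, b.atom2)
             for b in detect_interchain_bonds(salt_bridge_dimer)}
        b_ = {(b.kind, b.res1, b.res2, b.atom1, b.atom2)
              for b in detect_interchain_bonds(reordered)}
        assert a == b_

    def test_every_bond_spans_two_chains(self, core_pocket):
        s, _ = core_pocket
        for b in detect_interchain_bonds(s):
            assert b.res1[0] != b.res2[0]


class TestClashDetection:
    def test_matches_brute_force_scan(self, core_pocket):
        s, _ = core_pocket
        crit = BondCriteria()
        fast = set(c[:4] for c in detect_interchain_clashes(s, 0.77, crit))
        brute = set()
        entries = [(res, a) for res in s.residues() for a in res.atoms]
        for i, (ri, ai) in enumerate(entries):
            for rj, aj in entries[i + 1:]:
                if ri.chain_id == rj.chain_id:
                    continue
                d = np.linalg.norm(ai.coord - aj.coord)
                overlap = ai.vdw_radius + aj.vdw_radius - d
                if overlap < 0.77:
                    continue
                if ai.name == "SG" and aj.name == "SG" and d <= crit.disulfide_max:
                    continue
                k1, k2 = sorted([(ri.key, ai.name), (rj.key, aj.name)])
                brute.add((k1[0], k2[0], k1[1], k2[1]))
        assert fast == brute


class TestBendState:
    def test_extended_strand_is_straight(self):
        chain = build_chain("A", ["ALA"] * 7, "strand")
        s = Structure("s", {"A": chain})
        assert assign_bend_state(s, ("A", 4, "")) is False

    def test_engineered_turn_is_bent(self):
        turn = [(-139.0, 135.0), (-139.0, 135.0), (-60.0, -30.0), (-90.0, 0.0),
                (-139.0, 135.0), (-139.0, 135.0), (-139.0, 135.0)]
        chain = build_chain("A", ["ALA"] * 7, turn)
        s = Structure("s", {"A": chain})
        assert assign_bend_state(s, ("A", 4, "")) is True

    def test_helix_curvature_matches_direct_computation(self):
        chain = build_chain("A", ["ALA"] * 9, "helix")
        s = Structure("s", {"A": chain})
        ca = [r.atom("CA").coord for r in chain]
        v1, v2 = ca[4] - ca[2], ca[6] - ca[4]
        kappa = np.degrees(np.arccos(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert assign_bend_state(s, ("A", 5, "")) == bool(kappa > 70.0)

    def test_chain_terminus_reports_false(self):
        chain = build_chain("A", ["ALA"] * 5)
        s = Structure("s", {"A": chain})
        assert assign_bend_state(s, ("A", 1, "")) is False
        assert assign_bend_state(s, ("A", 5, "")) is False


class TestFeatureEvaluation:
    def test_self_mutation_triggers_nothing_at_every_site(self, salt_bridge_dimer):
        annotations = map_interface(salt_bridge_dimer, "A")
        for key, ann in annotations.items():
            if not ann.is_interface:
                continue
            res = salt_bridge_dimer.get_residue(key)
            v = VariantSpec(key[0], key[1], key[2], res.res_name, res.res_name)
            mut = build_mutant(salt_bridge_dimer, v)
            results = evaluate_features(salt_bridge_dimer, mut, ann)
            assert not [f for f in results if f.triggered]

    def test_rim_gating_makes_bond_features_inapplicable(self, rim_pocket):
        s, site = rim_pocket
        ann = map_interface(s, "A", attribute_partners=False)[site]
        mut = build_mutant(s, VariantSpec(site[0], site[1], site[2], "LYS", "ALA"))
        results = evaluate_features(s, mut, ann)
        by_id = {f.feature_id: f for f in results}
        for fid in CORE_SUPPORT_ONLY:
            assert by_id[fid].applicable is False
            assert by_id[fid].triggered is False

    def test_core_breakage_triggers_bridge_and_charge_features(self, core_pocket):
        s, site = core_pocket
        ann = map_interface(s, "A", attribute_partners=False)[site]
        mut = build_mutant(s, VariantSpec(site[0], site[1], site[2], "LYS", "ALA"))
        results = {f.feature_id: f for f in evaluate_features(s, mut, ann)}
        assert results[FeatureID.SALT_BRIDGE_BREAKAGE].triggered
        assert results[FeatureID.CHARGE_REPLACED].triggered
        impl = results[FeatureID.SALT_BRIDGE_BREAKAGE].implicated_residues
        assert site in impl and any(k[0] != site[0] for k in impl)

    def test_every_feature_reported_once(self, core_pocket):
        s, site = core_pocket
        ann = map_interface(s, "A", attribute_partners=False)[site]
        mut = build_mutant(s, VariantSpec(site[0], site[1], site[2], "LYS", "LYS"))
        results = evaluate_features(s, mut, ann)
        assert sorted(f.feature_id for f in results) == sorted(FeatureID)
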