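"""SASA correctness against closed-form geometry and an independent
implementation, plus the occlusion-monotonicity invariant."""

import numpy as np
import pytest

from ppi_missense.accessibility import SasaParams, atom_sasa, compute_rsa, compute_sasa
from ppi_missense.chem import MAX_ASA
from ppi_missense.fixtures import build_chain
from ppi_missense.geometry import rotation_about_axis
from ppi_missense.structure_model import Structure

PROBE = 1.4


def test_isolated_atom_matches_analytic_sphere():
    r = 1.70
    area = atom_sasa(np.zeros((1, 3)), np.array([r]))[0]
    expected = 4 * np.pi * (r + PROBE) ** 2
    assert area == pytest.approx(expected, rel=0.01)


def test_distant_atoms_are_fully_exposed():
    coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
    radii = np.array([1.70, 1.52])
    areas = atom_sasa(coords, radii)
    for a, r in zip(areas, radii):
        assert a == pytest.approx(4 * np.pi * (r + PROBE) ** 2, rel=0.01)


@pytest.mark.parametrize("d", [2.0, 3.0, 4.0, 5.0])
def test_two_sphere_overlap_matches_cap_formula(d):
    """Equal spheres at distance d bury a cap of height R - d/2 each."""
    r = 1.70
    R = r + PROBE
    areas = atom_sasa(np.array([[0.0, 0, 0], [d, 0, 0]]), np.array([r, r]))
    expected = 4 * np.pi * R * R - 2 * np.pi * R * (R - d / 2)
    assert areas[0] == pytest.approx(expected, rel=0.01)
    assert areas[1] == pytest.approx(expected, rel=0.01)


def test_occlusion_monotonicity_on_random_clouds():
    """Adding a second chain never increases any residue's accessibility."""
    from ppi_missense.structure_model import Atom, Residue

    rng = np.random.default_rng(42)
    for trial in range(100):
        pts_a = rng.uniform(-4, 4, size=(8, 3))
        pts_b = rng.uniform(-6, 6, size=(8, 3))
        def chain_of(pts, cid):
            residues = []
            for i, p in enumerate(pts):
                residues.append(Residue(cid, i + 1, "", "GLY",
                                        [Atom("CA", "C", p, 1.70)]))
            return residues
        a = chain_of(pts_a, "A")
        s_mono = Structure("m", {"A": [r.copy() for r in a]})
        s_cplx = Structure("c", {"A": a, "B": chain_of(pts_b, "B")})
        acc_m = compute_sasa(s_mono)
        acc_c = compute_sasa(s_cplx)
        for key, am in acc_m.items():
            assert acc_c[key].sasa <= am.sasa + 1e-9


def test_rotation_translation_invariance():
    chain = build_chain("A", ["GLY", "ALA", "SER", "ALA", "GLY"])
    s = Structure("s", {"A": chain})
    ref = compute_sasa(s)

    rot = rotation_about_axis(np.array([0.3, 1.0, -0.5]), 73.0)
    shift = np.array([11.0, -7.0, 3.0])
    moved = s.copy()
    for res in moved.residues():
        res.atoms = [a.moved_to(rot @ a.coord + shift) for a in res.atoms]
    got = compute_sasa(moved)
    # residue-level discretisation error of the 960-point lattice stays
    # under ~1.5% for a rigid motion; the total area is far tighter
    for key, acc in ref.items():
        assert got[key].sasa == pytest.approx(acc.sasa, rel=0.015)
    assert sum(a.sasa for a in got.values()) == pytest.approx(
        sum(a.sasa for a in ref.values()), rel=0.005)


def test_sampling_convergence():
    chain = build_chain("A", ["GLY", "ALA", "SER", "ALA", "GLY"])
    s = Structure("s", {"A": chain})
    coarse = compute_sasa(s, SasaParams(n_sphere_points=960))
    fine = compute_sasa(s, SasaParams(n_sphere_points=1920))
    for key in coarse:
        assert fine[key].sasa == pytest.approx(coarse[key].sasa, rel=0.01, abs=0.5)


class TestRsa:
    def test_reference_maximum_is_100_percent(self):
        assert compute_rsa(MAX_ASA["ALA"], "ALA") == pytest.approx(100.0)

    def test_zero_sasa_is_zero(self):
        assert compute_rsa(0.0, "TRP") == 0.0

    def test_unknown_residue_raises(self):
        with pytest.raises(KeyError):
            compute_rsa(10.0, "MSE")

    def test_extended_tripeptide_vs_independent_implementation(self):
        """Central residue of Gly-X-Gly agrees with biotite's SASA."""
        import biotite.structure as struc

        chain = build_chain("A", ["GLY", "ALA", "GLY"])
        atoms = []
        for res in chain:
            for a in res.atoms:
                at = struc.Atom(
                    a.coord, chain_id="A", res_id=res.seq_num,
                    res_name=res.res_name, atom_name=a.name, element=a.element,
                )
                atoms.append(at)
        arr = struc.array(atoms)
        per_atom = struc.sasa(arr, probe_radius=1.4, point_number=960,
                              vdw_radii="Single")
        central_biotite = per_atom[arr.res_id == 2].sum()

        s = Structure("gxg", {"A": chain})
        central_mine = compute_sasa(s)[("A", 2, "")].sasa
        assert central_mine == pytest.approx(central_biotite, rel=0.15)
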