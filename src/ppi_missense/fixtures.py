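"""Programmatic toy complexes with analytically known geometry.

Real interface benchmarks require curated experimental structures; for
testing, this module builds small multi-chain peptides with ideal
backbone geometry and side chains placed from the same internal
coordinate templates the mutant builder uses. Engineered interchain
contacts (hydrogen bond, salt bridge, disulfide, clash) are realised by
rigid placement of the partner chain, so every detector can be exercised
against ground truth that is true by construction, without downloading
anything.

Fixture chains use ideal φ/ψ templates (extended strand or α-helix) and
poly-alanine filler. Burial of the variant site is controlled by the
partner layout: a single facing lid leaves the site on the interface
rim, while an under-slab plus a scaffold ring of poly-glycine columns
buries it to interface-core levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import STANDARD_AA, element_of, vdw_radius
from .errors import FixtureGenerationError
from .geometry import place_atom, rotation_about_axis
from .mutant_builder import VariantSpec, build_sidechain
from .structure_model import Atom, Residue, ResidueKey, Structure

__all__ = ["FixtureSpec", "Contact", "make_dimer", "make_variant_panel",
           "build_chain", "make_pocket_dimer", "PanelEntry", "panel_manifest"]

# φ/ψ templates (degrees)
BACKBONE_TEMPLATES = {
    "strand": (-139.0, 135.0),
    "helix": (-57.0, -47.0),
}

# default residue types per engineered contact kind: (on A, on B)
CONTACT_RESIDUES = {
    "hbond": ("SER", "SER"),
    "salt_bridge": ("LYS", "GLU"),
    "disulfide": ("CYS", "CYS"),
    "clash": ("TRP", "TRP"),
}

# atom used as the "business end" of a residue's side chain
TIP_ATOMS = {
    "ALA": "CB", "ARG": "NH1", "ASN": "ND2", "ASP": "OD1", "CYS": "SG",
    "GLN": "NE2", "GLU": "OE1", "GLY": "CA", "HIS": "NE2", "ILE": "CD1",
    "LEU": "CD1", "LYS": "NZ", "MET": "CE", "PHE": "CZ", "PRO": "CG",
    "SER": "OG", "THR": "OG1", "TRP": "NE1", "TYR": "OH", "VAL": "CG1",
}


@dataclass(frozen=True)
class Contact:
    res_i: int  # 1-based residue number on chain A
    res_j: int  # 1-based residue number on chain B
    kind: str  # hbond | salt_bridge | disulfide | clash
    target_distance: float  # Å between the two tip atoms

    def __post_init__(self):
        if self.kind not in CONTACT_RESIDUES:
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.target_distance <= 0:
            raise ValueError("target_distance must be positive")


@dataclass
class FixtureSpec:
    n_residues_per_chain: int = 7
    backbone_template: str = "strand"  # "strand" | "helix"
    engineered_contacts: list[Contact] = field(default_factory=list)
    rng_seed: int = 0
    jitter: float = 0.0  # Å of seeded uniform placement noise (<= 0.05)
    separation: float = 50.0  # chain-chain distance when no contacts
    sequence_a: list[str] | None = None  # 3-letter codes, overrides poly-ALA
    sequence_b: list[str] | None = None


# ---------------------------------------------------------------------------
# ideal-geometry chain construction
# ---------------------------------------------------------------------------

_BB = {
    "N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231,
    "N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7, "CA_C_O": 120.8,
}


def build_chain(
    chain_id: str,
    sequence: list[str],
    template: str | list[tuple[float, float]] = "strand",
    chis: dict[int, tuple[float, ...]] | None = None,
    start_seq_num: int = 1,
) -> list[Residue]:
    """Build a peptide with ideal backbone geometry along ~+x.

    ``template`` is a named φ/ψ pair or an explicit per-residue list.
    ``chis`` maps 1-based sequence position (within this segment) to the
    chi angles of that residue's side chain; unlisted residues get
    all-trans side chains.
    """
    n = len(sequence)
    for aa in sequence:
        if aa not in STANDARD_AA:
            raise ValueError(f"unknown residue type {aa!r}")
    if isinstance(template, str):
        phi, psi = BACKBONE_TEMPLATES[template]
        angles = [(phi, psi)] * n
    else:
        angles = list(template)
        if len(angles) != n:
            raise ValueError("per-residue template length mismatch")
    chis = chis or {}

    # seed the first residue's backbone in the xy-plane
    npos = np.zeros(3)
    ca = np.array([_BB["N_CA"], 0.0, 0.0])
    ang = np.radians(180.0 - _BB["N_CA_C"])
    c = ca + _BB["CA_C"] * np.array([np.cos(ang), np.sin(ang), 0.0])

    backbones = [(npos, ca, c)]
    for i in range(1, n):
        phi_prev, psi_prev = angles[i - 1]
        n_prev, ca_prev, c_prev = backbones[-1]
        n_i = place_atom(n_prev, ca_prev, c_prev, _BB["C_N"], _BB["CA_C_N"], psi_prev)
        ca_i = place_atom(ca_prev, c_prev, n_i, _BB["N_CA"], _BB["C_N_CA"], 180.0)  # ω trans
        phi_i, _ = angles[i]
        c_i = place_atom(c_prev, n_i, ca_i, _BB["CA_C"], _BB["N_CA_C"], phi_i)
        backbones.append((n_i, ca_i, c_i))

    residues: list[Residue] = []
    for i, (aa, (n_i, ca_i, c_i)) in enumerate(zip(sequence, backbones)):
        _, psi_i = angles[i]
        o_i = place_atom(n_i, ca_i, c_i, _BB["C_O"], _BB["CA_C_O"], psi_i + 180.0)

        def mk(name, coord):
            elem = element_of(name)
            return Atom(name=name, element=elem, coord=np.asarray(coord, float),
                        vdw_radius=vdw_radius(elem))

        res = Residue(chain_id, start_seq_num + i, "", aa,
                      [mk("N", n_i), mk("CA", ca_i), mk("C", c_i), mk("O", o_i)])
        from .chem import N_CHI
        chi = chis.get(i + 1, tuple([180.0] * N_CHI[aa]))
        res.atoms.extend(build_sidechain(res, aa, chi))
        residues.append(res)

    # align the end-to-end CA axis with +x so that strands and helices
    # run straight and stacked copies form flat slabs
    if n >= 2:
        v = residues[-1].atom("CA").coord - residues[0].atom("CA").coord
        v = v / np.linalg.norm(v)
        target = np.array([1.0, 0.0, 0.0])
        axis = np.cross(v, target)
        norm = np.linalg.norm(axis)
        if norm > 1e-9:
            ang = np.degrees(np.arctan2(norm, float(np.dot(v, target))))
            transform_residues(residues, rot=rotation_about_axis(axis, ang))
    return residues


def transform_residues(residues: list[Residue], rot: np.ndarray | None = None,
                       trans: np.ndarray | None = None) -> None:
    """Apply a rigid motion in place."""
    rot = np.eye(3) if rot is None else rot
    trans = np.zeros(3) if trans is None else np.asarray(trans, float)
    for res in residues:
        res.atoms = [a.moved_to(rot @ a.coord + trans) for a in res.atoms]


def _orient_tip(residues: list[Residue], seq_num: int, direction: np.ndarray) -> None:
    """Rotate the chain about its x-axis so a residue's CA->tip vector
    projects onto the requested +/-y direction in the yz-plane."""
    res = next(r for r in residues if r.seq_num == seq_num)
    tip = TIP_ATOMS[res.res_name]
    v = res.atom(tip).coord - res.atom("CA").coord
    vyz = np.array([0.0, v[1], v[2]])
    if np.linalg.norm(vyz) < 1e-6:
        return
    target = np.asarray(direction, float)
    cur = np.arctan2(vyz[2], vyz[1])
    want = np.arctan2(target[2], target[1])
    transform_residues(residues, rot=rotation_about_axis(np.array([1.0, 0, 0]),
                                                         np.degrees(want - cur)))


def _apply_jitter(residues: list[Residue], jitter: float, rng: np.random.Generator) -> None:
    if jitter <= 0:
        return
    for res in residues:
        res.atoms = [
            a.moved_to(a.coord + rng.uniform(-jitter, jitter, 3)) for a in res.atoms
        ]


def make_dimer(spec: FixtureSpec) -> Structure:
    """Two-chain fixture realising the engineered contacts of the spec.

    The first contact fixes the rigid placement of chain B (its tip atom
    is set exactly ``target_distance`` above the chain-A tip along +y);
    any further contacts are verified to hold within ±0.1 Å and a
    :class:`FixtureGenerationError` names the first one that does not.
    """
    n = spec.n_residues_per_chain
    seq_a = list(spec.sequence_a) if spec.sequence_a else ["ALA"] * n
    seq_b = list(spec.sequence_b) if spec.sequence_b else ["ALA"] * n
    for c in spec.engineered_contacts:
        if not (1 <= c.res_i <= len(seq_a)) or not (1 <= c.res_j <= len(seq_b)):
            raise FixtureGenerationError(f"contact {c} outside chain bounds")
        aa_a, aa_b = CONTACT_RESIDUES[c.kind]
        if spec.sequence_a is None:
            seq_a[c.res_i - 1] = aa_a
        if spec.sequence_b is None:
            seq_b[c.res_j - 1] = aa_b

    chain_a = build_chain("A", seq_a, spec.backbone_template)
    chain_b = build_chain("B", seq_b, spec.backbone_template)

    if spec.engineered_contacts:
        first = spec.engineered_contacts[0]
        _orient_tip(chain_a, first.res_i, np.array([0.0, 1.0, 0.0]))
        _orient_tip(chain_b, first.res_j, np.array([0.0, 1.0, 0.0]))
        # flip B so its engineered side chain faces down toward A
        transform_residues(chain_b, rot=rotation_about_axis(np.array([1.0, 0, 0]), 180.0))
        res_a = next(r for r in chain_a if r.seq_num == first.res_i)
        res_b = next(r for r in chain_b if r.seq_num == first.res_j)
        tip_a = res_a.atom(TIP_ATOMS[res_a.res_name]).coord
        tip_b = res_b.atom(TIP_ATOMS[res_b.res_name]).coord
        shift = tip_a + np.array([0.0, first.target_distance, 0.0]) - tip_b
        transform_residues(chain_b, trans=shift)
    else:
        transform_residues(chain_b, trans=np.array([0.0, spec.separation, 0.0]))

    rng = np.random.default_rng(spec.rng_seed)
    _apply_jitter(chain_a, spec.jitter, rng)
    _apply_jitter(chain_b, spec.jitter, rng)

    s = Structure("fixture_dimer", {"A": chain_a, "B": chain_b}, source_path="<fixture>")

    for c in spec.engineered_contacts:
        res_a = next(r for r in chain_a if r.seq_num == c.res_i)
        res_b = next(r for r in chain_b if r.seq_num == c.res_j)
        d = np.linalg.norm(
            res_a.atom(TIP_ATOMS[res_a.res_name]).coord
            - res_b.atom(TIP_ATOMS[res_b.res_name]).coord
        )
        if abs(d - c.target_distance) > 0.1 + 2 * spec.jitter:
            raise FixtureGenerationError(
                f"contact {c} realised at {d:.2f} Å, wanted {c.target_distance:.2f}"
            )
    return s


# ---------------------------------------------------------------------------
# pocket dimers: controlled burial of the variant site
# ---------------------------------------------------------------------------

def _make_wall(
    chain_id: str,
    n_strands: int,
    strand_len: int,
    z_spacing: float,
    start_seq_num: int,
    special: tuple[int, str, tuple[float, ...]] | None = None,
) -> list[Residue]:
    """Parallel extended strands forming a flat slab in the xz-plane.

    ``special`` = (position-in-middle-strand, res_name, chis) swaps one
    filler residue of the middle strand for an interacting residue.
    """
    residues: list[Residue] = []
    seq_num = start_seq_num
    mid = n_strands // 2
    for k in range(n_strands):
        seq = ["ALA"] * strand_len
        chis: dict[int, tuple[float, ...]] = {}
        if special is not None and k == mid:
            pos, name, chi = special
            seq[pos - 1] = name
            chis[pos] = chi
        segment = build_chain(chain_id, seq, "strand", chis, start_seq_num=seq_num)
        transform_residues(segment, trans=np.array([0.0, 0.0, (k - mid) * z_spacing]))
        residues.extend(segment)
        seq_num += strand_len
    return residues


def make_pocket_dimer(
    site_aa: str,
    partner_aa: str | None = None,
    contact_distance: float = 3.0,
    burial: str = "core",
    site_chis: tuple[float, ...] | None = None,
    partner_chis: tuple[float, ...] | None = None,
    wall_gap: float = 5.5,
    under_gap: float = 3.5,
    n_strands: int = 3,
    strand_len: int = 9,
    site_backbone: str | list[tuple[float, float]] = "strand",
    flank_aa: str = "ALA",
    ring_radius: float = 6.0,
    seal_tight: bool = False,
) -> tuple[Structure, ResidueKey]:
    """Dimer with a controlled-burial variant site facing a partner lid.

    Chain A is a short strand whose middle residue is the variant site,
    oriented so its side chain points up (+y) at chain B. Chain B is a
    lid of parallel strands above the site; when ``partner_aa`` is given
    the lid residue directly above the site is that type with its side
    chain hanging down so its tip atom sits ``contact_distance`` Å from
    the site tip.

    ``burial="rim"`` keeps only the lid: the site loses accessibility but
    stays solvent exposed (interface rim). ``burial="core"`` additionally
    seals the site with a slab under chain A and a ring of vertical
    poly-glycine columns around the side-chain axis, burying the residue
    to interface-core levels while leaving the vertical contact axis
    free.
    """
    if burial not in ("core", "rim"):
        raise ValueError("burial must be 'core' or 'rim'")
    from .chem import N_CHI

    n_site = 7
    mid = n_site // 2 + 1
    seq_a = [flank_aa] * n_site
    seq_a[mid - 1] = site_aa
    chis_a = {}
    if site_chis is not None:
        chis_a[mid] = site_chis
    chain_a = build_chain("A", seq_a, site_backbone, chis_a)
    if burial == "rim":
        # flank strands make chain A a small sheet so that the facing
        # lid residues genuinely lose accessibility to it
        for k, z_off in ((1, -4.8), (2, 4.8)):
            flank = build_chain("A", [flank_aa] * n_site, "strand",
                                start_seq_num=100 * k + 1)
            transform_residues(flank, trans=np.array([0.0, 0.0, z_off]))
            chain_a.extend(flank)
    _orient_tip(chain_a, mid, np.array([0.0, 1.0, 0.0]))
    site_res = next(r for r in chain_a if r.seq_num == mid)
    tip_a = site_res.atom(TIP_ATOMS[site_aa]).coord

    wall_pos = strand_len // 2 + 1
    if partner_aa is not None:
        chi = partner_chis if partner_chis is not None else tuple([180.0] * N_CHI[partner_aa])
        special = (wall_pos, partner_aa, chi)
    else:
        special = None
    wall = _make_wall("B", n_strands, strand_len, 4.8, 1, special)

    if special is not None:
        mid_strand_first = (n_strands // 2) * strand_len + 1
        partner_seq = mid_strand_first + wall_pos - 1
        _orient_tip(wall, partner_seq, np.array([0.0, 1.0, 0.0]))
        transform_residues(wall, rot=rotation_about_axis(np.array([1.0, 0, 0]), 180.0))
        partner_res = next(r for r in wall if r.seq_num == partner_seq)
        tip_b = partner_res.atom(TIP_ATOMS[partner_aa]).coord
        shift = tip_a + np.array([0.0, contact_distance, 0.0]) - tip_b
        transform_residues(wall, trans=shift)
    else:
        # flat lid: backbone plane wall_gap above the site tip
        transform_residues(wall, rot=rotation_about_axis(np.array([1.0, 0, 0]), 180.0))
        wall_y = np.array([r.atom("CA").coord[1] for r in wall]).mean()
        ca_x = np.array([r.atom("CA").coord[0] for r in wall]).mean()
        ca_z = np.array([r.atom("CA").coord[2] for r in wall]).mean()
        shift = np.array([tip_a[0] - ca_x, tip_a[1] + wall_gap - wall_y, tip_a[2] - ca_z])
        transform_residues(wall, trans=shift)

    chains_b = list(wall)
    if burial == "core":
        next_seq = 1 + len(wall)
        a_x = site_res.atom("CA").coord[0]
        a_z = site_res.atom("CA").coord[2]
        a_plane = float(np.mean([r.atom("CA").coord[1] for r in chain_a]))

        # slab under chain A sealing the site from below
        under = _make_wall("B", n_strands, strand_len, 4.8, start_seq_num=next_seq)
        a_y = min(a.coord[1] for a in site_res.atoms)
        u_y = np.array([r.atom("CA").coord[1] for r in under]).mean()
        u_x = np.array([r.atom("CA").coord[0] for r in under]).mean()
        u_z = np.array([r.atom("CA").coord[2] for r in under]).mean()
        transform_residues(under, trans=np.array(
            [a_x - u_x, a_y - under_gap - u_y, a_z - u_z]))
        chains_b.extend(under)
        next_seq += len(under)

        # ring of vertical poly-Gly columns around the side-chain axis:
        # buries the whole shaft regardless of its length while keeping
        # the vertical contact axis open
        sidechain = site_res.sidechain
        if sidechain:
            axis_xz = np.array([
                np.mean([a.coord[0] for a in sidechain]),
                np.mean([a.coord[2] for a in sidechain]),
            ])
            # columns rise into the lid slab itself so the ring-lid
            # junction has no crack wider than a voxel
            lid_top = max(a.coord[1] for r in wall for a in r.atoms)
            base_y = a_plane + 1.8
            span = max(lid_top - base_y + 1.0, 3.8)
            n_col = int(np.ceil(span / 3.8)) + 1
            scaffold: list[Residue] = []
            col_seq = 1
            for angle in np.arange(0.0, 360.0, 22.5):
                theta = np.radians(angle)
                col = build_chain("C", ["GLY"] * n_col, "strand",
                                  start_seq_num=col_seq)
                # turn the strand vertical (+x -> +y), then spin it about
                # its own axis so the carbonyl bulge points outward,
                # keeping the ring interior smooth
                transform_residues(col, rot=rotation_about_axis(
                    np.array([0.0, 0.0, 1.0]), 90.0))
                allc = np.array([a.coord for r in col for a in r.atoms])
                centre = allc.mean(axis=0)
                o_dir = np.mean([a.coord - centre for r in col for a in r.atoms
                                 if a.name == "O"], axis=0)
                cur_ang = np.degrees(np.arctan2(o_dir[2], o_dir[0]))
                transform_residues(col, rot=rotation_about_axis(
                    np.array([0.0, 1.0, 0.0]), angle - cur_ang))
                base = np.array([a.coord for r in col for a in r.atoms])
                col_x = base[:, 0].mean()
                col_ymin = base[:, 1].min()
                col_z = base[:, 2].mean()
                transform_residues(col, trans=np.array([
                    axis_xz[0] + ring_radius * np.cos(theta) - col_x,
                    base_y - col_ymin,
                    axis_xz[1] + ring_radius * np.sin(theta) - col_z,
                ]))
                scaffold.extend(col)
                col_seq += n_col
            # low strips either side of the chain-A strand close the seam
            # between the under-slab and the ring base
            seam = [(-3.0, -0.8), (3.0, -0.8)]
            if seal_tight:
                seam += [(-4.4, -1.6), (4.4, -1.6), (-2.2, 0.8), (2.2, 0.8),
                         (-4.4, 0.6), (4.4, 0.6)]
            for z_off, y_off in seam:
                strip = build_chain("B", ["ALA"] * strand_len, "strand",
                                    start_seq_num=next_seq)
                s_x = np.array([r.atom("CA").coord[0] for r in strip]).mean()
                s_y = np.array([r.atom("CA").coord[1] for r in strip]).mean()
                s_z = np.array([r.atom("CA").coord[2] for r in strip]).mean()
                transform_residues(strip, trans=np.array(
                    [a_x - s_x, a_plane + y_off - s_y, a_z + z_off - s_z]))
                chains_b.extend(strip)
                next_seq += strand_len

    chains = {"A": chain_a, "B": chains_b}
    if burial == "core" and site_res.sidechain:
        # the ring is its own scaffold chain so that partner residues of
        # chain B remain genuine interface residues of B
        chains["C"] = scaffold
    s = Structure("fixture_pocket", chains, source_path="<fixture>")
    return s, site_res.key


# ---------------------------------------------------------------------------
# labelled variant panel
# ---------------------------------------------------------------------------

@dataclass
class PanelEntry:
    name: str
    structure: Structure
    variant: VariantSpec
    expected_verdict: str  # "damaging" | "neutral" | "not_interface"
    expected_features: frozenset  # of FeatureID
    note: str = ""


def make_variant_panel(rng_seed: int = 0) -> list[PanelEntry]:
    """Labelled fixture panel covering the whole damage-feature catalogue.

    Every feature appears with a trigger case; bond/charge features also
    get a rim-gated control (same chemistry, rim-level burial, feature
    inapplicable), and the panel carries neutral controls and a
    far-from-interface case. Expected labels are true by construction of
    the geometry: where burying a polar side chain necessarily hydrogen
    bonds it to the surrounding partner shell, the corresponding bond
    feature is part of the expectation (a real buried substitution
    behaves the same way).
    """
    from .feature_catalogue import FeatureID

    panel: list[PanelEntry] = []

    def entry(name, built, variant, verdict, features, note=""):
        s, site = built
        var = VariantSpec.from_strings(site[0], site[1], *variant, icode=site[2])
        panel.append(PanelEntry(name, s, var, verdict, frozenset(features), note))

    entry(
        "hbond_breakage_core",
        make_pocket_dimer("SER", "SER", 2.8, "core"),
        ("SER", "ALA"),
        "damaging", {FeatureID.HBOND_BREAKAGE},
        "wild-type interchain hydroxyl hydrogen bond removed by Ser->Ala",
    )
    entry(
        "hbond_formation_core",
        make_pocket_dimer("ALA", "SER", 4.2, "core"),
        ("ALA", "SER"),
        "damaging", {FeatureID.HBOND_FORMATION},
        "mutant OG lands within the H-bond cutoff of the partner hydroxyl",
    )
    entry(
        "saltbridge_breakage_core",
        make_pocket_dimer("LYS", "GLU", 3.0, "core"),
        ("LYS", "ALA"),
        "damaging", {FeatureID.SALT_BRIDGE_BREAKAGE, FeatureID.CHARGE_REPLACED,
                     FeatureID.HBOND_BREAKAGE},
        "engineered interchain Lys-Glu bridge removed along with the "
        "ammonium's hydrogen bond to a partner carbonyl; charge lost",
    )
    entry(
        "saltbridge_rim_gated",
        make_pocket_dimer("LYS", "GLU", 3.0, "rim"),
        ("LYS", "ALA"),
        "damaging", {FeatureID.CAVITY_ALTERATION},
        "identical chemistry at rim burial: bond and charge features are "
        "inapplicable; only the packing defect left by the lost side chain "
        "registers",
    )
    entry(
        "saltbridge_formation_core",
        make_pocket_dimer("MET", "GLU", 3.8, "core"),
        ("MET", "LYS"),
        "damaging", {FeatureID.SALT_BRIDGE_FORMATION, FeatureID.HBOND_FORMATION},
        "like-for-like length swap: the new ammonium reaches the partner "
        "carboxylate the methionine could not bond, picking up backbone "
        "acceptors alongside",
    )
    entry(
        "disulfide_breakage_core",
        make_pocket_dimer("CYS", "CYS", 2.05, "core"),
        ("CYS", "ALA"),
        "damaging", {FeatureID.DISULFIDE_BREAKAGE},
        "interchain SG-SG covalent bond removed",
    )
    entry(
        "charge_switch_core",
        make_pocket_dimer("LYS", None, burial="core"),
        ("LYS", "GLU"),
        "damaging", {FeatureID.CHARGE_SWITCH, FeatureID.HBOND_BREAKAGE,
                     FeatureID.HBOND_FORMATION, FeatureID.STERIC_CLASH},
        "buried interface lysine flipped to glutamate: the ammonium's "
        "hydrogen bonds break, the carboxylate finds backbone amides, and "
        "the stiffer head group strains against the partner shell",
    )
    entry(
        "unbalanced_charge_core",
        make_pocket_dimer("MET", None, burial="core"),
        ("MET", "ARG"),
        "damaging", {FeatureID.UNBALANCED_CHARGE, FeatureID.HBOND_FORMATION,
                     FeatureID.STERIC_CLASH},
        "Met->Arg wedges an uncompensated guanidinium into the pocket: new "
        "donor bonds to partner backbone and steric strain come with it",
    )
    entry(
        "gly_replaced_rim",
        make_pocket_dimer("GLY", None, burial="rim", wall_gap=5.6),
        ("GLY", "ALA"),
        "damaging", {FeatureID.GLY_REPLACED},
        "interface glycine substituted",
    )
    entry(
        "tyr_replaced_rim",
        make_pocket_dimer("TYR", None, burial="rim"),
        ("TYR", "PHE"),
        "damaging", {FeatureID.TYR_REPLACED},
        "interface tyrosine substituted",
    )
    entry(
        "trp_replaced_rim",
        make_pocket_dimer("TRP", None, burial="rim"),
        ("TRP", "ALA"),
        "damaging", {FeatureID.TRP_REPLACED, FeatureID.CAVITY_ALTERATION},
        "interface tryptophan substituted, leaving unwettable space under "
        "the partner lid",
    )
    entry(
        "pro_introduced_rim",
        make_pocket_dimer("ALA", None, burial="rim"),
        ("ALA", "PRO"),
        "damaging", {FeatureID.PRO_INTRODUCED},
        "proline placed in the interface backbone",
    )
    turn = [(-139.0, 135.0), (-139.0, 135.0), (-60.0, -30.0), (-90.0, 0.0),
            (-139.0, 135.0), (-139.0, 135.0), (-139.0, 135.0)]
    entry(
        "gly_in_bend_rim",
        make_pocket_dimer("GLY", None, burial="rim", wall_gap=5.6,
                          site_backbone=turn),
        ("GLY", "ALA"),
        "damaging", {FeatureID.GLY_REPLACED, FeatureID.GLY_IN_BEND},
        "glycine in a turn backbone replaced",
    )
    entry(
        "steric_clash_core",
        make_pocket_dimer("ALA", None, burial="core", wall_gap=4.0),
        ("ALA", "PHE"),
        "damaging", {FeatureID.STERIC_CLASH},
        "bulky phenylalanine jammed under the partner lid",
    )
    entry(
        "cavity_alteration_core",
        make_pocket_dimer("TRP", None, burial="core"),
        ("TRP", "GLY"),
        "damaging", {FeatureID.TRP_REPLACED, FeatureID.CAVITY_ALTERATION,
                     FeatureID.HBOND_BREAKAGE},
        "removing the enclosed tryptophan leaves an interfacial void and "
        "severs the indole NH bond to a partner carbonyl",
    )
    entry(
        "self_mutation_control",
        make_pocket_dimer("LYS", "GLU", 3.0, "core"),
        ("LYS", "LYS"),
        "neutral", set(),
        "self-mutation triggers nothing",
    )
    entry(
        "conservative_control",
        make_pocket_dimer("ILE", None, burial="core"),
        ("ILE", "VAL"),
        "neutral", set(),
        "conservative apolar substitution at a quiet interface",
    )
    far = make_dimer(FixtureSpec(n_residues_per_chain=7, engineered_contacts=[],
                                 separation=50.0, rng_seed=rng_seed))
    panel.append(PanelEntry(
        "far_surface_site",
        far,
        VariantSpec.from_strings("A", 4, "ALA", "ARG"),
        "not_interface", frozenset(),
        "chains 50 Å apart: any mutation is outside the interface",
    ))
    return panel


def panel_manifest(panel: list[PanelEntry]) -> str:
    """TSV manifest of a variant panel."""
    lines = ["name\tchain\tseq_num\twt\tmut\texpected_verdict\texpected_features\tnote"]
    for e in panel:
        feats = ",".join(sorted(f.value for f in e.expected_features)) or "-"
        v = e.variant
        lines.append(
            f"{e.name}\t{v.chain_id}\t{v.seq_num}\t{v.wt_aa}\t{v.mut_aa}\t"
            f"{e.expected_verdict}\t{feats}\t{e.note}"
        )
    return "\n".join(lines) + "\n"
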