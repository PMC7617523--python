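"""Interchain interaction detection and the structural-damage feature set.

The catalogue compares a wild-type complex with its repacked mutant model
and reports, for each feature, whether it is applicable at the variant's
interface category and whether it triggered. Bond-, charge- and
cavity-type comparisons are made against a *repacked wild type* (the
deterministic self-mutant of the same site) rather than the raw input
coordinates, so that differences reflect the substitution and not the
side-chain rebuilding itself; a self-mutation therefore triggers nothing
by construction.

Charge- and bond-related features (H-bond / salt-bridge / disulfide
breakage and formation, charge replaced / switched / unbalanced) are only
applicable on core and support residues; identity and packing features
(Gly/Tyr/Trp replaced, Pro introduced, Gly in a bend, steric clash,
cavity alteration) apply to any interface residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .chem import (
    HBOND_ACCEPTORS,
    HBOND_DONORS,
    NEGATIVE_ATOMS,
    POSITIVE_ATOMS,
    formal_charge_sign,
)
from .interface_map import InterfaceAnnotation, InterfaceCategory
from .mutant_builder import MutantModel, RepackParams, VariantSpec, build_mutant
from .structure_model import Residue, ResidueKey, Structure, min_heavy_atom_distance

__all__ = [
    "BondCriteria", "InterchainBond", "FeatureID", "FeatureResult",
    "detect_interchain_bonds", "detect_interchain_clashes",
    "assign_bend_state", "interfacial_void_volume", "evaluate_features",
    "CATALOGUE_VERSION",
]

CATALOGUE_VERSION = "15-feature-v1"


@dataclass(frozen=True)
class BondCriteria:
    hbond_da_max: float = 3.5  # Å, donor-acceptor heavy-atom distance
    saltbridge_max: float = 4.0  # Å, charged-group heavy-atom distance
    disulfide_max: float = 2.5  # Å, SG-SG
    model_allowance: float = 1.0  # Å added to H-bond and salt-bridge cutoffs
    clash_overlap_min: float = 0.77  # Å of vdW overlap counting as a clash
    cavity_change_min: float = 70.0  # Å³ of interfacial void change
    contact_radius: float = 5.0  # Å, residue-residue contact definition

    @property
    def hbond_cutoff(self) -> float:
        return self.hbond_da_max + self.model_allowance

    @property
    def saltbridge_cutoff(self) -> float:
        return self.saltbridge_max + self.model_allowance


@dataclass(frozen=True)
class InterchainBond:
    kind: str  # "hbond" | "salt_bridge" | "disulfide"
    res1: ResidueKey
    res2: ResidueKey
    atom1: str
    atom2: str
    distance: float

    def involves(self, key: ResidueKey) -> bool:
        return self.res1 == key or self.res2 == key

    def partner_of(self, key: ResidueKey) -> tuple[ResidueKey, str]:
        """(partner residue, partner atom) as seen from ``key``."""
        if self.res1 == key:
            return self.res2, self.atom2
        if self.res2 == key:
            return self.res1, self.atom1
        raise ValueError(f"bond does not involve {key}")


class FeatureID(str, Enum):
    HBOND_BREAKAGE = "interface_hbond_breakage"
    HBOND_FORMATION = "interface_hbond_formation"
    SALT_BRIDGE_BREAKAGE = "interface_salt_bridge_breakage"
    SALT_BRIDGE_FORMATION = "interface_salt_bridge_formation"
    DISULFIDE_BREAKAGE = "interface_disulfide_breakage"
    CHARGE_REPLACED = "interface_charge_replaced"
    CHARGE_SWITCH = "interface_charge_switch"
    UNBALANCED_CHARGE = "interface_unbalanced_charge_introduced"
    GLY_REPLACED = "interface_gly_replaced"
    TYR_REPLACED = "interface_tyr_replaced"
    TRP_REPLACED = "interface_trp_replaced"
    PRO_INTRODUCED = "interface_pro_introduced"
    GLY_IN_BEND = "interface_gly_in_bend"
    STERIC_CLASH = "interface_steric_clash"
    CAVITY_ALTERATION = "interface_cavity_alteration"


#: Features applicable only on core / support residues (bond and charge
#: chemistry matters where the interface is buried, not on the solvated rim).
CORE_SUPPORT_ONLY = frozenset({
    FeatureID.HBOND_BREAKAGE,
    FeatureID.HBOND_FORMATION,
    FeatureID.SALT_BRIDGE_BREAKAGE,
    FeatureID.SALT_BRIDGE_FORMATION,
    FeatureID.DISULFIDE_BREAKAGE,
    FeatureID.CHARGE_REPLACED,
    FeatureID.CHARGE_SWITCH,
    FeatureID.UNBALANCED_CHARGE,
})


@dataclass
class FeatureResult:
    feature_id: FeatureID
    triggered: bool
    applicable: bool
    implicated_residues: set[ResidueKey] = field(default_factory=set)
    evidence: str = ""

    def __post_init__(self):
        if self.triggered and not self.applicable:
            raise ValueError("a feature cannot trigger while inapplicable")


# ---------------------------------------------------------------------------
# Interchain bond detection
# ---------------------------------------------------------------------------

def _polar_atoms(res: Residue, table: dict[str, tuple[str, ...]], backbone_atom: str | None):
    names = set(table.get(res.res_name, ()))
    if backbone_atom:
        names.add(backbone_atom)
        if backbone_atom == "O" and res.has_atom("OXT"):
            names.add("OXT")
    return [a for a in res.atoms if a.name in names]


def _charged_atoms(res: Residue, sign: int):
    table = POSITIVE_ATOMS if sign > 0 else NEGATIVE_ATOMS
    return [a for a in res.atoms if a.name in table.get(res.res_name, ())]


def detect_interchain_bonds(
    s: Structure,
    query_chain: str | None = None,
    crit: BondCriteria = BondCriteria(),
) -> list[InterchainBond]:
    """All hydrogen bonds, salt bridges and disulfides spanning two chains.

    Detection is heavy-atom distance only (no hydrogens, no angle term).
    A donor-acceptor pair whose atoms belong to oppositely charged groups
    is reported once, as a salt bridge, never double-counted as a
    hydrogen bond. Disulfides take no model allowance.
    """
    residues = list(s.residues())
    bonds: list[InterchainBond] = []
    seen_pairs: set[tuple] = set()

    def add(kind, r1: Residue, a1, r2: Residue, a2, d):
        if r1.key > r2.key or (r1.key == r2.key and a1.name > a2.name):
            r1, a1, r2, a2 = r2, a2, r1, a1
        pair = (r1.key, a1.name, r2.key, a2.name)
        if pair in seen_pairs:
            return
        seen_pairs.add(pair)
        bonds.append(InterchainBond(kind, r1.key, r2.key, a1.name, a2.name, float(d)))

    for i, r1 in enumerate(residues):
        for r2 in residues[i + 1:]:
            if r1.chain_id == r2.chain_id:
                continue
            if query_chain is not None and query_chain not in (r1.chain_id, r2.chain_id):
                continue
            if min_heavy_atom_distance(r1, r2) > max(crit.hbond_cutoff, crit.saltbridge_cutoff):
                continue
            # salt bridges first: they pre-empt H-bond double counting
            for ra, rb in ((r1, r2), (r2, r1)):
                for ap in _charged_atoms(ra, +1):
                    for an in _charged_atoms(rb, -1):
                        d = np.linalg.norm(ap.coord - an.coord)
                        if d <= crit.saltbridge_cutoff:
                            add("salt_bridge", ra, ap, rb, an, d)
            # disulfides
            if r1.res_name == "CYS" and r2.res_name == "CYS":
                if r1.has_atom("SG") and r2.has_atom("SG"):
                    d = np.linalg.norm(r1.atom("SG").coord - r2.atom("SG").coord)
                    if d <= crit.disulfide_max:
                        add("disulfide", r1, r1.atom("SG"), r2, r2.atom("SG"), d)
            # hydrogen bonds
            for donor_res, acc_res in ((r1, r2), (r2, r1)):
                donors = _polar_atoms(donor_res, HBOND_DONORS, "N")
                acceptors = _polar_atoms(acc_res, HBOND_ACCEPTORS, "O")
                for da in donors:
                    d_charged = da.name in POSITIVE_ATOMS.get(donor_res.res_name, ())
                    for aa in acceptors:
                        a_charged = aa.name in NEGATIVE_ATOMS.get(acc_res.res_name, ())
                        if d_charged and a_charged:
                            continue  # that pair is salt-bridge territory
                        d = np.linalg.norm(da.coord - aa.coord)
                        if d <= crit.hbond_cutoff:
                            add("hbond", donor_res, da, acc_res, aa, d)
    bonds.sort(key=lambda b: (b.res1, b.res2, b.atom1, b.atom2, b.kind))
    return bonds


def detect_interchain_clashes(
    s: Structure,
    min_overlap: float = 0.77,
    crit: BondCriteria = BondCriteria(),
) -> list[tuple[ResidueKey, ResidueKey, str, str, float]]:
    """Interchain heavy-atom pairs overlapping beyond ``min_overlap`` Å.

    Genuine covalent interchain links (disulfide SG-SG pairs within the
    disulfide cutoff) are not counted as clashes.
    """
    entries = [(res, a) for res in s.residues() for a in res.atoms]
    coords = np.array([a.coord for _, a in entries], float)
    radii = np.array([a.vdw_radius for _, a in entries], float)
    tree = cKDTree(coords)
    out = []
    max_pair = 2 * radii.max() if len(radii) else 0.0
    for i, j in tree.query_pairs(max_pair):
        ri, ai = entries[i]
        rj, aj = entries[j]
        if ri.chain_id == rj.chain_id:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        overlap = radii[i] + radii[j] - d
        if overlap < min_overlap:
            continue
        if ai.name == "SG" and aj.name == "SG" and d <= crit.disulfide_max:
            continue
        k1, k2 = sorted([(ri.key, ai.name), (rj.key, aj.name)])
        out.append((k1[0], k2[0], k1[1], k2[1], float(overlap)))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Backbone bend state
# ---------------------------------------------------------------------------

def assign_bend_state(s: Structure, site: ResidueKey) -> bool:
    """True when the backbone kinks at the site (DSSP-style bend).

    The curvature angle is measured between the CA(i-2)->CA(i) and
    CA(i)->CA(i+2) directions; a bend is an angle above 70 degrees.
    Residues closer than two positions to a chain terminus (or with
    missing CA atoms in the window) report False.
    """
    chain = s.chains.get(site[0], [])
    idx = next((i for i, r in enumerate(chain) if r.key == site), None)
    if idx is None or idx < 2 or idx + 2 >= len(chain):
        return False
    window = chain[idx - 2: idx + 3]
    if not all(r.has_atom("CA") for r in window):
        return False
    ca = [r.atom("CA").coord for r in window]
    v1 = ca[2] - ca[0]
    v2 = ca[4] - ca[2]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    kappa = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return bool(kappa > 70.0)


# ---------------------------------------------------------------------------
# Interfacial void volume
# ---------------------------------------------------------------------------

def interfacial_void_volume(
    s: Structure,
    grid_spacing: float = 1.0,
    probe_radius: float = 1.4,
    interface_margin: float = 6.0,
) -> float:
    """Volume (Å³) of empty, solvent-inaccessible space near the interface.

    A regular grid is laid over the structure; a voxel is *empty* when it
    lies outside every van der Waals sphere, and *solvent-swept* when it
    is within the probe radius of a probe-sized position connected to
    bulk solvent (flood fill from the box boundary). Empty voxels that
    are not solvent-swept and lie within ``interface_margin`` of at least
    two different chains constitute the interfacial void.
    """
    entries = [(res.chain_id, a) for res in s.residues() for a in res.atoms]
    coords = np.array([a.coord for _, a in entries], float)
    radii = np.array([a.vdw_radius for _, a in entries], float)
    chain_ids = sorted({cid for cid, _ in entries})
    if len(chain_ids) < 2:
        return 0.0

    pad = probe_radius + 2.0
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    axes = [np.arange(lo[k], hi[k] + grid_spacing, grid_spacing) for k in range(3)]
    shape = tuple(len(ax) for ax in axes)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    tree = cKDTree(coords)
    k = min(16, len(coords))
    dists, idx = tree.query(points, k=k)
    if k == 1:
        dists = dists[:, None]
        idx = idx[:, None]
    surf = (dists - radii[idx]).min(axis=1).reshape(shape)

    # solvent-excluded void: empty voxels (outside every vdW sphere) that
    # a water probe cannot wet. Probe positions are voxels with at least
    # probe_radius of clearance; positions connected to the box boundary
    # are bulk solvent, and everything within one probe radius of bulk is
    # swept. What remains — crevices too narrow for water and enclosed
    # pockets — is the void.
    empty = surf >= 0.0
    probe_ok = surf >= probe_radius
    labels, _ = ndimage.label(probe_ok)
    boundary_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary_labels.update(np.unique(labels[tuple(sl)]))
    boundary_labels.discard(0)
    open_solvent = np.isin(labels, sorted(boundary_labels))

    reach = max(1, int(np.floor(probe_radius / grid_spacing + 1e-9)))
    ball = np.zeros((2 * reach + 1,) * 3, bool)
    rng = np.arange(-reach, reach + 1)
    bx, by, bz = np.meshgrid(rng, rng, rng, indexing="ij")
    ball[(bx ** 2 + by ** 2 + bz ** 2) * grid_spacing ** 2 <= probe_radius ** 2 + 1e-9] = True
    swept = ndimage.binary_dilation(open_solvent, structure=ball)
    enclosed = empty & ~swept

    near = np.zeros(len(points), int)
    for cid in chain_ids:
        mask = np.array([c == cid for c, _ in entries])
        ctree = cKDTree(coords[mask])
        d, _ = ctree.query(points, k=1)
        near += (d <= interface_margin).astype(int)
    interfacial = (near >= 2).reshape(shape)

    return float((enclosed & interfacial).sum()) * grid_spacing ** 3


# ---------------------------------------------------------------------------
# Feature evaluation
# ---------------------------------------------------------------------------

def _partner_contacts(s: Structure, site: ResidueKey, radius: float) -> set[ResidueKey]:
    """Partner-chain residues with a heavy atom within ``radius`` of the site."""
    site_res = s.get_residue(site)
    out = set()
    for res in s.residues():
        if res.chain_id == site[0]:
            continue
        if min_heavy_atom_distance(site_res, res) < radius:
            out.add(res.key)
    return out


def _bond_identities(bonds: list[InterchainBond], site: ResidueKey, kind: str):
    """Comparable identity of each bond of ``kind`` involving the site."""
    return {
        (b.partner_of(site)[0], b.partner_of(site)[1]): b
        for b in bonds
        if b.kind == kind and b.involves(site)
    }


def evaluate_features(
    wt: Structure,
    mut: MutantModel,
    annot: InterfaceAnnotation,
    crit: BondCriteria = BondCriteria(),
    repack_params: RepackParams = RepackParams(),
    baseline: MutantModel | None = None,
) -> list[FeatureResult]:
    """Evaluate the full damage-feature catalogue for one variant.

    ``baseline`` is the repacked self-mutant of the same site; when not
    supplied it is built here with the same repacking parameters as the
    mutant, so the comparison isolates the substitution from repacking
    noise.
    """
    if annot.category is InterfaceCategory.NON_INTERFACE:
        raise ValueError("feature evaluation requires an interface residue")
    variant = mut.variant
    site = variant.site
    if baseline is None:
        self_variant = VariantSpec(variant.chain_id, variant.seq_num, variant.icode,
                                   variant.wt_aa, variant.wt_aa)
        baseline = build_mutant(wt, self_variant, repack_params)

    base_s = baseline.structure
    mut_s = mut.structure
    cat_ok_bonds = annot.category in (InterfaceCategory.CORE, InterfaceCategory.SUPPORT)

    # identity features implicate the wild type's own interface contacts,
    # taken from the input coordinates rather than the repacked baseline
    contacts_wt = _partner_contacts(wt, site, crit.contact_radius)
    contacts_mut = _partner_contacts(mut_s, site, crit.contact_radius)

    bonds_base = detect_interchain_bonds(base_s, site[0], crit)
    bonds_mut = detect_interchain_bonds(mut_s, site[0], crit)

    results: list[FeatureResult] = []

    def bond_diff_feature(fid: FeatureID, kind: str, direction: str):
        before = _bond_identities(bonds_base, site, kind)
        after = _bond_identities(bonds_mut, site, kind)
        if direction == "lost":
            diff = {k: before[k] for k in before.keys() - after.keys()}
            verb = "lost"
        else:
            diff = {k: after[k] for k in after.keys() - before.keys()}
            verb = "formed"
        applicable = cat_ok_bonds
        triggered = applicable and bool(diff)
        implicated = {site} | {partner for (partner, _atom) in diff} if triggered else set()
        evidence = "; ".join(
            f"{kind} {verb}: {b.atom1}({b.res1[0]}{b.res1[1]})-"
            f"{b.atom2}({b.res2[0]}{b.res2[1]}) at {b.distance:.2f} A"
            for b in diff.values()
        )
        results.append(FeatureResult(fid, triggered, applicable, implicated, evidence))

    bond_diff_feature(FeatureID.HBOND_BREAKAGE, "hbond", "lost")
    bond_diff_feature(FeatureID.HBOND_FORMATION, "hbond", "formed")
    bond_diff_feature(FeatureID.SALT_BRIDGE_BREAKAGE, "salt_bridge", "lost")
    bond_diff_feature(FeatureID.SALT_BRIDGE_FORMATION, "salt_bridge", "formed")
    bond_diff_feature(FeatureID.DISULFIDE_BREAKAGE, "disulfide", "lost")

    wt_sign = formal_charge_sign(variant.wt_aa)
    mut_sign = formal_charge_sign(variant.mut_aa)

    def identity_feature(fid: FeatureID, triggered_if: bool, evidence: str,
                         core_support_only: bool = False, contacts: set | None = None):
        applicable = cat_ok_bonds if core_support_only else True
        triggered = applicable and triggered_if
        base_contacts = contacts if contacts is not None else contacts_wt
        implicated = ({site} | base_contacts) if triggered else set()
        results.append(FeatureResult(fid, triggered, applicable, implicated,
                                     evidence if triggered else ""))

    identity_feature(
        FeatureID.CHARGE_REPLACED,
        wt_sign != 0 and mut_sign == 0,
        f"charged {variant.wt_aa} replaced by neutral {variant.mut_aa}",
        core_support_only=True,
    )
    identity_feature(
        FeatureID.CHARGE_SWITCH,
        wt_sign * mut_sign == -1,
        f"formal charge sign flips: {variant.wt_aa} -> {variant.mut_aa}",
        core_support_only=True,
    )

    # unbalanced charge: neutral -> charged with no compensating partner
    unbalanced = False
    if cat_ok_bonds and wt_sign == 0 and mut_sign != 0:
        mut_res = mut_s.get_residue(site)
        charged = _charged_atoms(mut_res, mut_sign)
        opposite_found = False
        for res in mut_s.residues():
            if res.chain_id == site[0]:
                continue
            opp = _charged_atoms(res, -mut_sign)
            if charged and opp and cdist(
                np.array([a.coord for a in charged]),
                np.array([a.coord for a in opp]),
            ).min() <= crit.saltbridge_cutoff:
                opposite_found = True
                break
        unbalanced = not opposite_found
    identity_feature(
        FeatureID.UNBALANCED_CHARGE,
        unbalanced,
        f"{variant.mut_aa} introduces an uncompensated "
        f"{'positive' if mut_sign > 0 else 'negative'} interface charge",
        core_support_only=True,
        contacts=contacts_mut,
    )

    gly_replaced = variant.wt_aa == "GLY" and variant.mut_aa != "GLY"
    identity_feature(FeatureID.GLY_REPLACED, gly_replaced,
                     f"interface glycine replaced by {variant.mut_aa}")
    identity_feature(FeatureID.TYR_REPLACED,
                     variant.wt_aa == "TYR" and variant.mut_aa != "TYR",
                     f"interface tyrosine replaced by {variant.mut_aa}")
    identity_feature(FeatureID.TRP_REPLACED,
                     variant.wt_aa == "TRP" and variant.mut_aa != "TRP",
                     f"interface tryptophan replaced by {variant.mut_aa}")
    identity_feature(FeatureID.PRO_INTRODUCED,
                     variant.mut_aa == "PRO" and variant.wt_aa != "PRO",
                     "proline introduced at the interface backbone")
    identity_feature(FeatureID.GLY_IN_BEND,
                     gly_replaced and assign_bend_state(wt, site),
                     "replaced glycine sits in a backbone bend")

    clashes_base = {c[:4]: c[4] for c in
                    detect_interchain_clashes(base_s, crit.clash_overlap_min, crit)}
    clashes_mut = {c[:4]: c[4] for c in
                   detect_interchain_clashes(mut_s, crit.clash_overlap_min, crit)}
    new_clashes = {k: v for k, v in clashes_mut.items() if k not in clashes_base}
    clash_trig = bool(new_clashes)
    clash_impl = {site} if clash_trig else set()
    for (r1, r2, _a1, _a2) in new_clashes:
        clash_impl |= {r1, r2}
    worst = max(new_clashes.values(), default=0.0)
    results.append(FeatureResult(
        FeatureID.STERIC_CLASH, clash_trig, True, clash_impl,
        (f"{len(new_clashes)} new interchain clash pair(s), "
         f"worst overlap {worst:.2f} A") if clash_trig else "",
    ))

    v_base = interfacial_void_volume(base_s)
    v_mut = interfacial_void_volume(mut_s)
    dv = v_mut - v_base
    cav_trig = abs(dv) >= crit.cavity_change_min
    results.append(FeatureResult(
        FeatureID.CAVITY_ALTERATION, cav_trig, True,
        ({site} | contacts_wt | contacts_mut) if cav_trig else set(),
        (f"interfacial void volume changes by {dv:+.0f} A^3") if cav_trig else "",
    ))

    return results
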