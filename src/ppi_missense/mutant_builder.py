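"""Mutant model construction by shell stripping and greedy rotamer repacking.

The mutant is built on a frozen backbone: the wild-type side chain at the
variant site and every side chain within the repack shell (any residue,
any chain, with a heavy-atom pair closer than ``shell_radius`` to the
site) are removed, the mutant side chain is introduced from ideal
internal coordinates, and the stripped shell is rebuilt by a greedy
lowest-clash search over a compact backbone-independent rotamer library.

The packer is deliberately simple and fully deterministic — no random
number generator, fixed residue order (increasing distance from the
variant site), fixed rotamer enumeration order — so identical inputs give
bit-identical models. The packing backend is pluggable: any callable
honouring the same contract (backbone invariance, single-position
sequence change) can replace the built-in greedy packer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .chem import (
    AA_1TO3,
    N_CHI,
    SIDECHAIN_TEMPLATES,
    STANDARD_AA,
    element_of,
    rotamer_chi_sets,
    vdw_radius,
)
from .errors import VariantMismatchError
from .geometry import place_atom
from .structure_model import Atom, Residue, ResidueKey, Structure, min_heavy_atom_distance

__all__ = ["VariantSpec", "RepackParams", "MutantModel", "select_repack_shell", "build_mutant", "build_sidechain"]


@dataclass(frozen=True)
class VariantSpec:
    chain_id: str
    seq_num: int
    icode: str
    wt_aa: str  # 3-letter code
    mut_aa: str  # 3-letter code

    def __post_init__(self):
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in STANDARD_AA:
                raise ValueError(f"unknown amino-acid code {aa!r}")

    @classmethod
    def from_strings(cls, chain_id: str, seq_num: int, wt: str, mut: str, icode: str = "") -> "VariantSpec":
        """Accept one- or three-letter amino-acid codes."""
        def norm(code: str) -> str:
            code = code.strip().upper()
            return AA_1TO3[code] if len(code) == 1 else code
        return cls(chain_id, int(seq_num), icode.strip(), norm(wt), norm(mut))

    @property
    def site(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def is_self(self) -> bool:
        return self.wt_aa == self.mut_aa


@dataclass(frozen=True)
class RepackParams:
    shell_radius: float = 5.0  # Å, strict "closer than" test
    rotamer_set: str = "staggered-v1"
    clash_tolerance: float = 0.4  # Å of allowed vdW overlap while packing
    max_iterations: int = 3

    def __post_init__(self):
        if self.shell_radius <= 0:
            raise ValueError("shell_radius must be positive")


@dataclass
class MutantModel:
    structure: Structure
    variant: VariantSpec
    repacked_residues: list[ResidueKey]
    packing_score: float
    strained_residues: list[ResidueKey] = field(default_factory=list)


def select_repack_shell(s: Structure, site: ResidueKey, radius: float = 5.0) -> list[ResidueKey]:
    """Residues (any chain) with a heavy atom strictly closer than ``radius``
    to any heavy atom of the site residue, plus the site itself.

    Measured on wild-type coordinates; deterministic (chain, seq_num,
    icode) order.
    """
    site_res = s.get_residue(site)
    shell = {site}
    for res in s.residues():
        if res.key == site:
            continue
        if min_heavy_atom_distance(site_res, res) < radius:
            shell.add(res.key)
    return sorted(shell)


def build_sidechain(residue: Residue, res_name: str, chis: tuple[float, ...]) -> list[Atom]:
    """Side-chain heavy atoms from ideal internal coordinates.

    Requires backbone N, CA, C on the residue. Glycine yields no atoms.
    """
    template = SIDECHAIN_TEMPLATES[res_name]
    if not template:
        return []
    pos: dict[str, np.ndarray] = {
        "N": residue.atom("N").coord,
        "CA": residue.atom("CA").coord,
        "C": residue.atom("C").coord,
    }
    atoms: list[Atom] = []
    for name, (a, b, c), bond, angle, torsion in template:
        if isinstance(torsion, tuple):
            _, k, offset = torsion
            tor = chis[k - 1] + offset
        else:
            tor = torsion
        coord = place_atom(pos[a], pos[b], pos[c], bond, angle, tor)
        pos[name] = coord
        elem = element_of(name)
        atoms.append(Atom(name=name, element=elem, coord=coord, vdw_radius=vdw_radius(elem)))
    return atoms


def _atom_charge(res_name: str, atom_name: str) -> int:
    from .chem import NEGATIVE_ATOMS, POSITIVE_ATOMS
    if atom_name in POSITIVE_ATOMS.get(res_name, ()):
        return 1
    if atom_name in NEGATIVE_ATOMS.get(res_name, ()):
        return -1
    return 0


class _Environment:
    """Mutable atom set the packer scores candidate rotamers against."""

    def __init__(self):
        self.coords: list[np.ndarray] = []
        self.radii: list[float] = []
        self.elems: list[str] = []
        self.charge: list[int] = []
        self.owner: list[tuple[str, int, str]] = []
        self.is_backbone: list[bool] = []

    def add(self, res_key: ResidueKey, res_name: str, atom: Atom):
        self.coords.append(atom.coord)
        self.radii.append(atom.vdw_radius)
        self.elems.append(atom.element)
        self.charge.append(_atom_charge(res_name, atom.name))
        self.owner.append(res_key)
        self.is_backbone.append(not atom.is_sidechain)

    def arrays(self):
        return (
            np.array(self.coords, float).reshape(-1, 3),
            np.array(self.radii, float),
            np.array(self.elems, dtype=object),
            np.array(self.charge, int),
        )


def _chain_neighbours(s: Structure, key: ResidueKey) -> set[ResidueKey]:
    """Keys of the sequence-adjacent residues in the same chain."""
    chain = s.chains.get(key[0], [])
    out: set[ResidueKey] = set()
    for i, res in enumerate(chain):
        if res.key == key:
            if i > 0:
                out.add(chain[i - 1].key)
            if i + 1 < len(chain):
                out.add(chain[i + 1].key)
            break
    return out


# Rotamer scoring: squared vdW overlap penalty plus a small reward for
# polar contacts at hydrogen-bonding distance, so that among clash-free
# rotamers the one restoring (or making) a polar interaction is chosen
# deterministically over an arbitrary staggered well. Sulfur pairs at
# disulfide distance are covalent, not clashing, and are rewarded too.
POLAR_BONUS_WEIGHT = 0.3
CHARGE_BONUS_WEIGHT = 0.7
POLAR_CONTACT_MIN = 2.4  # Å — closer than this is a clash, not a bond
POLAR_CONTACT_MAX = 3.6  # Å
CHARGE_CONTACT_MAX = 4.0  # Å, salt-bridge range
DISULFIDE_SS_MAX = 2.5  # Å


def _rotamer_score(
    cand_coords: np.ndarray,
    cand_radii: np.ndarray,
    cand_elems: np.ndarray,
    cand_charge: np.ndarray,
    env_coords: np.ndarray,
    env_radii: np.ndarray,
    env_elems: np.ndarray,
    env_charge: np.ndarray,
    mask: np.ndarray,
    tolerance: float,
) -> float:
    """Clash penalty minus polar/ionic contact reward for one rotamer."""
    if not len(env_coords) or not mask.any() or not len(cand_coords):
        return 0.0
    ec = env_coords[mask]
    er = env_radii[mask]
    ee = env_elems[mask]
    eq = env_charge[mask]
    d = cdist(cand_coords, ec)
    overlap = cand_radii[:, None] + er[None, :] - d - tolerance

    ss_pair = (cand_elems[:, None] == "S") & (ee[None, :] == "S")
    disulfide = ss_pair & (d <= DISULFIDE_SS_MAX)
    overlap[disulfide] = 0.0
    score = float((np.maximum(overlap, 0.0) ** 2).sum())

    cand_polar = np.isin(cand_elems, ("N", "O"))
    env_polar = np.isin(ee, ("N", "O"))
    polar_pair = cand_polar[:, None] & env_polar[None, :]
    n_polar = int((polar_pair & (d >= POLAR_CONTACT_MIN) & (d <= POLAR_CONTACT_MAX)).sum())
    n_polar += int(disulfide.sum())
    # salt bridges are rewarded above plain polar contacts so that an
    # ion pair present in the input survives repacking
    ionic = (cand_charge[:, None] * eq[None, :] < 0) & (d >= POLAR_CONTACT_MIN) & (d <= CHARGE_CONTACT_MAX)
    return score - POLAR_BONUS_WEIGHT * n_polar - CHARGE_BONUS_WEIGHT * int(ionic.sum())


def _clash_overlap_sum(
    cand_coords: np.ndarray,
    cand_radii: np.ndarray,
    cand_elems: np.ndarray,
    env_coords: np.ndarray,
    env_radii: np.ndarray,
    env_elems: np.ndarray,
    tolerance: float,
) -> float:
    """Pure squared-overlap penalty (disulfide S-S pairs excluded)."""
    if not len(env_coords) or not len(cand_coords):
        return 0.0
    d = cdist(cand_coords, env_coords)
    overlap = cand_radii[:, None] + env_radii[None, :] - d - tolerance
    ss = (cand_elems[:, None] == "S") & (env_elems[None, :] == "S") & (d <= DISULFIDE_SS_MAX)
    overlap[ss] = 0.0
    return float((np.maximum(overlap, 0.0) ** 2).sum())


def build_mutant(
    s: Structure,
    variant: VariantSpec,
    params: RepackParams = RepackParams(),
) -> MutantModel:
    """Construct the repacked mutant model.

    The backbone is untouched everywhere; only side chains inside the
    repack shell change. A residue whose best rotamer still overlaps the
    fixed environment by more than the clash tolerance is kept at its
    best-available rotamer and flagged as strained.
    """
    site_res_wt = s.get_residue(variant.site)
    if site_res_wt.res_name != variant.wt_aa:
        raise VariantMismatchError(
            f"residue {variant.site} is {site_res_wt.res_name}, "
            f"variant says wild type {variant.wt_aa}"
        )

    shell = select_repack_shell(s, variant.site, params.shell_radius)
    # pack order: increasing wild-type distance from the site, ties by key
    dist = {
        key: (0.0 if key == variant.site
              else min_heavy_atom_distance(site_res_wt, s.get_residue(key)))
        for key in shell
    }
    order = sorted(shell, key=lambda k: (dist[k], k))

    mut = s.copy()
    site_res = mut.get_residue(variant.site)
    site_res.res_name = variant.mut_aa

    # strip shell side chains (backbone retained bit-identically)
    packable: list[ResidueKey] = []
    wt_sidechains: dict[ResidueKey, list[Atom]] = {}
    for key in order:
        res = mut.get_residue(key)
        if res.res_name not in SIDECHAIN_TEMPLATES:
            continue  # non-standard residue: side chain left untouched
        if not (res.has_atom("N") and res.has_atom("CA") and res.has_atom("C")):
            continue  # incomplete backbone: cannot rebuild, leave as-is
        wt_sidechains[key] = [a for a in res.atoms if a.is_sidechain]
        res.atoms = [a for a in res.atoms if not a.is_sidechain]
        packable.append(key)

    # fixed environment: all backbones plus untouched (non-shell) side
    # chains — the shell was stripped in place just above
    env = _Environment()
    for res in mut.residues():
        for a in res.atoms:
            env.add(res.key, res.res_name, a)

    env_coords, env_radii, env_elems, env_charge = env.arrays()
    env_owner = env.owner
    neighbours = {key: _chain_neighbours(mut, key) for key in packable}

    # initial placement: keep the wild-type conformation wherever the
    # residue type is unchanged (minimal-perturbation repacking); the
    # mutated site starts empty and is built on the first sweep
    placed: dict[ResidueKey, list[Atom]] = {}
    for key in packable:
        if key == variant.site and not variant.is_self:
            placed[key] = []
        else:
            placed[key] = list(wt_sidechains[key])
    strained: set[ResidueKey] = set()

    def res_charges(res_name: str, atoms: list[Atom]) -> np.ndarray:
        return np.array([_atom_charge(res_name, a.name) for a in atoms], int)

    def other_sidechain_arrays(skip: ResidueKey):
        coords, radii, elems, charges, owners = [], [], [], [], []
        for key, atoms in placed.items():
            if key == skip:
                continue
            rn = mut.get_residue(key).res_name
            for a in atoms:
                coords.append(a.coord)
                radii.append(a.vdw_radius)
                elems.append(a.element)
                charges.append(_atom_charge(rn, a.name))
                owners.append(key)
        return (
            np.array(coords, float).reshape(-1, 3),
            np.array(radii, float),
            np.array(elems, dtype=object),
            np.array(charges, int),
            owners,
        )

    def candidate_arrays(res_name: str, atoms: list[Atom]):
        return (
            np.array([a.coord for a in atoms], float),
            np.array([a.vdw_radius for a in atoms], float),
            np.array([a.element for a in atoms], dtype=object),
            res_charges(res_name, atoms),
        )

    def residue_env_mask(key: ResidueKey) -> np.ndarray:
        # exclude every atom of the residue itself and the backbone of
        # sequence neighbours (covalently linked, inherently close)
        skip_keys = {key} | neighbours[key]
        mask = np.array([o not in skip_keys or not bb
                         for o, bb in zip(env_owner, env.is_backbone)], bool)
        mask &= np.array([o != key for o in env_owner], bool)
        return mask

    for _ in range(max(1, params.max_iterations)):
        changed = False
        for key in order:
            if key not in placed:
                continue
            res = mut.get_residue(key)
            env_mask = residue_env_mask(key)
            sc_coords, sc_radii, sc_elems, sc_charge, sc_owners = other_sidechain_arrays(key)
            sc_mask = np.ones(len(sc_owners), bool)

            def score_of(atoms: list[Atom]) -> float:
                if not atoms:
                    return 0.0
                cc, cr, ce, cq = candidate_arrays(res.res_name, atoms)
                s = _rotamer_score(cc, cr, ce, cq, env_coords, env_radii,
                                   env_elems, env_charge, env_mask,
                                   params.clash_tolerance)
                s += _rotamer_score(cc, cr, ce, cq, sc_coords, sc_radii,
                                    sc_elems, sc_charge, sc_mask,
                                    params.clash_tolerance)
                return s

            # the incumbent conformation (wild type, or the previous
            # sweep's choice) is kept unless a rotamer is strictly better
            best_atoms = placed[key]
            best_score = score_of(best_atoms) if best_atoms else (
                0.0 if not SIDECHAIN_TEMPLATES[res.res_name] else np.inf)
            for chis in rotamer_chi_sets(res.res_name):
                atoms = build_sidechain(res, res.res_name, chis)
                score = score_of(atoms)
                if score < best_score - 1e-9:
                    best_score, best_atoms = score, atoms
            if best_atoms is not placed[key]:
                changed = True
                placed[key] = best_atoms
        if not changed:
            break

    for key in packable:
        res = mut.get_residue(key)
        res.atoms = res.backbone + placed[key]

    # final packing score: residual vdW overlap of the placed shell side
    # chains against everything else (polar reward excluded)
    def residual_overlap(key: ResidueKey) -> float:
        atoms = placed[key]
        if not atoms:
            return 0.0
        cc, cr, ce, _ = candidate_arrays(mut.get_residue(key).res_name, atoms)
        env_mask = residue_env_mask(key)
        total = _clash_overlap_sum(cc, cr, ce, env_coords[env_mask],
                                   env_radii[env_mask], env_elems[env_mask],
                                   params.clash_tolerance)
        sc_coords, sc_radii, sc_elems, _, sc_owners = other_sidechain_arrays(key)
        total += 0.5 * _clash_overlap_sum(cc, cr, ce, sc_coords, sc_radii, sc_elems,
                                          params.clash_tolerance)
        return total

    total_score = 0.0
    for key in packable:
        score = residual_overlap(key)
        total_score += score
        if score > 1e-9:
            strained.add(key)

    return MutantModel(
        structure=mut,
        variant=variant,
        repacked_residues=sorted(packable),
        packing_score=total_score,
        strained_residues=sorted(strained),
    )
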