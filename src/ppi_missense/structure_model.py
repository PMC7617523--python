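"""Chain / residue / atom data model and PDB I/O.

The in-memory model is deliberately small: heavy atoms only, author
numbering preserved, one selected model, altlocs resolved at parse time.
File reading and writing are delegated to :mod:`gemmi`; this module owns
the translation into the package's own types and the geometric primitives
consumed by every downstream stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .chem import BACKBONE_ATOMS, STANDARD_AA, element_of, vdw_radius
from .errors import ChainNotFoundError, EmptyStructureError, InputError, ResidueNotFoundError

#: (chain_id, seq_num, insertion_code) — insertion code "" when absent.
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    vdw_radius: float
    occupancy: float = 1.0

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_ATOMS

    def moved_to(self, coord: np.ndarray) -> "Atom":
        return replace(self, coord=np.asarray(coord, float))


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    is_standard: bool = True
    low_confidence: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.insertion_code)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.key} ({self.res_name})")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], float).reshape(-1, 3)

    @property
    def backbone(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_sidechain]

    @property
    def sidechain(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_sidechain]

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id, self.seq_num, self.insertion_code, self.res_name,
            list(self.atoms), self.is_standard, self.low_confidence,
        )


@dataclass
class Structure:
    structure_id: str
    chains: dict[str, list[Residue]]
    source_path: str = ""

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def residues(self):
        for residues in self.chains.values():
            yield from residues

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def get_residue(self, key: ResidueKey) -> Residue:
        chain_id, seq_num, icode = key
        if chain_id not in self.chains:
            raise ChainNotFoundError(chain_id)
        for res in self.chains[chain_id]:
            if res.seq_num == seq_num and res.insertion_code == icode:
                return res
        raise ResidueNotFoundError(key)

    def copy(self) -> "Structure":
        return Structure(
            self.structure_id,
            {cid: [r.copy() for r in residues] for cid, residues in self.chains.items()},
            self.source_path,
        )

    def all_atoms(self) -> list[tuple[Residue, Atom]]:
        return [(res, a) for res in self.residues() for a in res.atoms]


def _resolve_altlocs(raw_atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in raw_atoms:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve first-seen order
    seen: list[gemmi.Atom] = []
    names_done: set[str] = set()
    for atom in raw_atoms:
        if atom.name in names_done:
            continue
        names_done.add(atom.name)
        seen.append(best[atom.name])
    return seen


def parse_structure(path, model_index: int = 0) -> Structure:
    """Read a PDB file into the package data model.

    Hydrogens and waters are dropped, altlocs resolved to the
    highest-occupancy conformer, and only the model selected by
    ``model_index`` is loaded. Non-standard amino-acid residues are kept
    but flagged (and excluded from interface analysis downstream);
    non-polymer heteroatoms are skipped.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise InputError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    if model_index >= len(st):
        raise InputError(f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.is_water():
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            standard = res.name in STANDARD_AA
            if not is_aa and not standard:
                continue  # non-polymer heteroatom group
            if not standard:
                warnings.warn(
                    f"non-standard residue {res.name} at "
                    f"({chain.name}, {res.seqid.num}{res.seqid.icode.strip()}); "
                    "kept but flagged",
                    stacklevel=2,
                )
            atoms: list[Atom] = []
            for atom in _resolve_altlocs([a for a in res if not a.is_hydrogen()]):
                elem = atom.element.name.upper() if atom.element.name else element_of(atom.name)
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=elem,
                        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z], float),
                        vdw_radius=vdw_radius(elem),
                        occupancy=float(atom.occ),
                    )
                )
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(chain.name, res.seqid.num, icode, res.name, atoms, is_standard=standard)
            )
        if residues:
            existing = chains.setdefault(chain.name, [])
            existing.extend(residues)

    if not chains:
        raise EmptyStructureError(f"no protein residues in {path}")
    return Structure(structure_id=str(getattr(st, "name", "")) or "structure",
                     chains=chains, source_path=str(path))


def write_structure(s: Structure, path) -> None:
    """Write the structure as a single-model PDB file (3-decimal coords)."""
    if s.n_residues == 0:
        raise ValueError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = s.structure_id
    model = gemmi.Model("1")
    for chain_id, residues in s.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_num, res.insertion_code or " ")
            gres.het_flag = "A" if res.is_standard else "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*(float(x) for x in a.coord))
                ga.occ = a.occupancy
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise InputError(f"cannot write PDB file {path}: {exc}") from exc


def extract_monomer(s: Structure, chain_id: str) -> Structure:
    """Single-chain view with coordinates bit-identical to the complex."""
    if chain_id not in s.chains:
        raise ChainNotFoundError(chain_id)
    return Structure(
        structure_id=f"{s.structure_id}_{chain_id}",
        chains={chain_id: [r.copy() for r in s.chains[chain_id]]},
        source_path=s.source_path,
    )


def min_heavy_atom_distance(r1: Residue, r2: Residue) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs (symmetric)."""
    if not r1.atoms or not r2.atoms:
        raise ValueError("residue without atoms")
    return float(cdist(r1.coords(), r2.coords()).min())
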