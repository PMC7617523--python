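"""Interface residue identification and core / rim / support categorisation.

A residue of the query chain is an interface residue when it loses at
least ``delta_rsa_min`` percentage points of relative solvent
accessibility on complex formation (monomer RSA minus complex RSA).
Interface residues are then split by the buried/exposed threshold
``buried_rsa_threshold``:

* **core** — exposed in the monomer (RSA >= threshold), buried in the
  complex (RSA < threshold);
* **rim** — exposed in both forms;
* **support** — buried in both forms.

Complex RSA is computed against all partner chains simultaneously, so a
multimer interface (for instance a residue occluded by two subunits of a
homotetramer) is handled in one pass; per-partner attribution is done by
pairwise removal afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .accessibility import SasaParams, compute_sasa
from .chem import SIDECHAIN_ATOMS
from .errors import ChainNotFoundError, NoPartnerChainError
from .structure_model import ResidueKey, Structure, extract_monomer

__all__ = ["InterfaceCategory", "InterfaceParams", "InterfaceAnnotation",
           "categorize", "map_interface", "interface_table"]


class InterfaceCategory(str, Enum):
    CORE = "core"
    RIM = "rim"
    SUPPORT = "support"
    NON_INTERFACE = "non_interface"


@dataclass(frozen=True)
class InterfaceParams:
    delta_rsa_min: float = 5.0  # percentage points lost on binding
    buried_rsa_threshold: float = 9.0  # exposed/buried boundary, percent
    partner_restore_min: float = 1.0  # attribution: pp restored on removal

    def __post_init__(self):
        if self.delta_rsa_min <= 0 or self.buried_rsa_threshold <= 0:
            raise ValueError("interface thresholds must be positive")


@dataclass
class InterfaceAnnotation:
    residue_key: ResidueKey
    res_name: str
    rsa_monomer: float
    rsa_complex: float
    category: InterfaceCategory
    partner_chains: frozenset[str] = frozenset()
    low_confidence: bool = False

    @property
    def is_interface(self) -> bool:
        return self.category is not InterfaceCategory.NON_INTERFACE


def categorize(rsa_m: float, rsa_c: float, params: InterfaceParams = InterfaceParams()) -> InterfaceCategory:
    """Pure categorisation from monomer/complex RSA.

    Boundary semantics: the exposed test ``rsa >= threshold`` is
    inclusive, the buried test ``rsa < threshold`` exclusive, and the
    interface test ``rsa_m - rsa_c >= delta`` inclusive.
    """
    if rsa_c > rsa_m + 1e-9:
        raise ValueError(
            f"rsa_complex ({rsa_c}) exceeds rsa_monomer ({rsa_m}): "
            "occlusion cannot increase accessibility — upstream bug"
        )
    t = params.buried_rsa_threshold
    if rsa_m - rsa_c < params.delta_rsa_min:
        return InterfaceCategory.NON_INTERFACE
    if rsa_m >= t:
        return InterfaceCategory.CORE if rsa_c < t else InterfaceCategory.RIM
    return InterfaceCategory.SUPPORT


def _incomplete_sidechain(res) -> bool:
    expected = SIDECHAIN_ATOMS.get(res.res_name)
    if not expected:
        return False
    present = sum(1 for name in expected if res.has_atom(name))
    return present < 0.5 * len(expected)


def map_interface(
    complex_structure: Structure,
    query_chain: str,
    params: InterfaceParams = InterfaceParams(),
    sasa_params: SasaParams = SasaParams(),
    attribute_partners: bool = True,
    complex_access=None,
) -> dict[ResidueKey, InterfaceAnnotation]:
    """Annotate every residue of the query chain against all partners.

    ``complex_access`` may carry a precomputed whole-assembly
    accessibility map (from :func:`compute_sasa` on the same structure
    and parameters) to avoid recomputing it when several chains of one
    complex are mapped in turn.
    """
    if query_chain not in complex_structure.chains:
        raise ChainNotFoundError(query_chain)
    partner_ids = [c for c in complex_structure.chain_ids if c != query_chain]
    if not partner_ids:
        raise NoPartnerChainError(
            "interface mapping requires a complex with at least two chains"
        )

    monomer = extract_monomer(complex_structure, query_chain)
    acc_mono = compute_sasa(monomer, sasa_params, context="monomer")
    acc_cplx = complex_access if complex_access is not None else compute_sasa(
        complex_structure, sasa_params, context="complex")

    annotations: dict[ResidueKey, InterfaceAnnotation] = {}
    interface_keys: list[ResidueKey] = []
    for res in complex_structure.chains[query_chain]:
        key = res.key
        am, ac = acc_mono[key], acc_cplx[key]
        if am.rsa is None or ac.rsa is None:
            continue  # non-standard residue: flagged at parse, excluded here
        # clip tiny negative sampling noise on the buried side
        rsa_c = min(ac.rsa, am.rsa)
        cat = categorize(am.rsa, rsa_c, params)
        annotations[key] = InterfaceAnnotation(
            key, res.res_name, am.rsa, rsa_c, cat,
            low_confidence=_incomplete_sidechain(res),
        )
        if cat is not InterfaceCategory.NON_INTERFACE:
            interface_keys.append(key)

    if interface_keys:
        if len(partner_ids) == 1:
            only = frozenset(partner_ids)
            for key in interface_keys:
                annotations[key].partner_chains = only
        elif attribute_partners:
            _attribute_partner_chains(
                complex_structure, query_chain, partner_ids,
                annotations, interface_keys, params, sasa_params,
            )
    return annotations


def _attribute_partner_chains(complex_structure, query_chain, partner_ids,
                              annotations, interface_keys, params, sasa_params):
    """A partner chain is credited when removing it restores accessibility.

    For each partner P the complex SASA is recomputed without P; chains
    whose removal restores at least ``partner_restore_min`` percentage
    points of a residue's RSA are recorded as occluding partners.
    """
    restored: dict[ResidueKey, set[str]] = {k: set() for k in interface_keys}
    for pid in partner_ids:
        reduced = Structure(
            complex_structure.structure_id,
            {cid: residues for cid, residues in complex_structure.chains.items() if cid != pid},
            complex_structure.source_path,
        )
        acc = compute_sasa(reduced, sasa_params, context="complex")
        for key in interface_keys:
            ann = annotations[key]
            rsa_without = acc[key].rsa
            if rsa_without is not None and rsa_without - ann.rsa_complex >= params.partner_restore_min:
                restored[key].add(pid)
    for key in interface_keys:
        chains = restored[key]
        if not chains:
            # occlusion only visible jointly; credit all partners
            chains = set(partner_ids)
        annotations[key].partner_chains = frozenset(chains)


def interface_table(annotations: dict[ResidueKey, InterfaceAnnotation]) -> str:
    """TSV export of an interface annotation map."""
    lines = ["chain\tseq_num\ticode\tres_name\trsa_monomer\trsa_complex\tcategory\tpartner_chains"]
    for key in sorted(annotations, key=lambda k: (k[0], k[1], k[2])):
        a = annotations[key]
        partners = ",".join(sorted(a.partner_chains)) or "-"
        lines.append(
            f"{key[0]}\t{key[1]}\t{key[2]}\t{a.res_name}\t"
            f"{a.rsa_monomer:.2f}\t{a.rsa_complex:.2f}\t{a.category.value}\t{partners}"
        )
    return "\n".join(lines) + "\n"
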