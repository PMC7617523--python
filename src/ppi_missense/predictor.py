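"""End-to-end pipeline: interface mapping, mutant modelling, feature
evaluation and the damaging/neutral verdict.

A variant is called **damaging** when at least one triggered damage
feature affects two or more interchain residues: the feature's implicated
residue set, restricted to residues that are interface residues of their
own chain, must contain the variant site plus at least one further
residue (typically a partner-chain contact). Variants at residues that
lose no accessibility on complex formation are reported as
``not_interface`` without building a mutant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .accessibility import SasaParams, compute_sasa
from .errors import PipelineError, PPIMissenseError
from .feature_catalogue import (
    CATALOGUE_VERSION,
    BondCriteria,
    FeatureResult,
    evaluate_features,
)
from .interface_map import (
    InterfaceAnnotation,
    InterfaceCategory,
    InterfaceParams,
    map_interface,
)
from .mutant_builder import MutantModel, RepackParams, VariantSpec, build_mutant
from .structure_model import ResidueKey, Structure

__all__ = ["PipelineParams", "Prediction", "predict", "render_report", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class PipelineParams:
    """Bundle of every tunable threshold in the pipeline."""

    sasa: SasaParams = field(default_factory=SasaParams)
    interface: InterfaceParams = field(default_factory=InterfaceParams)
    repack: RepackParams = field(default_factory=RepackParams)
    bonds: BondCriteria = field(default_factory=BondCriteria)
    min_interchain_residues: int = 2  # damaging rule: implicated interface residues


@dataclass
class Prediction:
    variant: VariantSpec
    verdict: str  # "damaging" | "neutral" | "not_interface"
    category: InterfaceCategory
    rsa_monomer: float
    rsa_complex: float
    partner_chains: tuple[str, ...]
    features: list[FeatureResult] = field(default_factory=list)
    rationale: str = ""
    mutant: MutantModel | None = None

    @property
    def triggered_features(self) -> list[FeatureResult]:
        return [f for f in self.features if f.triggered]


def _interface_residue_set(
    complex_structure: Structure,
    params: PipelineParams,
    chains: set[str],
    complex_access=None,
) -> set[ResidueKey]:
    """Keys of all interface residues, per chain against all partners."""
    out: set[ResidueKey] = set()
    for chain_id in chains:
        annotations = map_interface(
            complex_structure, chain_id, params.interface, params.sasa,
            attribute_partners=False, complex_access=complex_access,
        )
        out.update(k for k, a in annotations.items() if a.is_interface)
    return out


def predict(
    complex_structure: Structure,
    variant: VariantSpec,
    params: PipelineParams = PipelineParams(),
) -> Prediction:
    """Run the full pipeline for one variant on a multi-chain structure."""
    try:
        complex_access = compute_sasa(complex_structure, params.sasa, context="complex")
        annotations = map_interface(
            complex_structure, variant.chain_id, params.interface, params.sasa,
            complex_access=complex_access,
        )
    except PPIMissenseError as exc:
        raise PipelineError("interface_mapping", exc) from exc

    site_ann = annotations.get(variant.site)
    if site_ann is None:
        raise PipelineError(
            "interface_mapping",
            KeyError(f"variant site {variant.site} not annotated "
                     "(missing or non-standard residue)"),
        )

    if not site_ann.is_interface:
        return Prediction(
            variant=variant,
            verdict="not_interface",
            category=InterfaceCategory.NON_INTERFACE,
            rsa_monomer=site_ann.rsa_monomer,
            rsa_complex=site_ann.rsa_complex,
            partner_chains=(),
            rationale=(
                f"residue loses only {site_ann.rsa_monomer - site_ann.rsa_complex:.1f} "
                "percentage points of RSA on complex formation "
                f"(< {params.interface.delta_rsa_min:g} required)"
            ),
        )

    try:
        mutant = build_mutant(complex_structure, variant, params.repack)
    except PPIMissenseError as exc:
        raise PipelineError("mutant_building", exc) from exc

    try:
        features = evaluate_features(
            complex_structure, mutant, site_ann, params.bonds, params.repack,
        )
    except PPIMissenseError as exc:
        raise PipelineError("feature_evaluation", exc) from exc

    # damaging rule: some triggered feature must implicate >= 2 interface
    # residues (counted across chains, the site included)
    implicated_chains = {k[0] for f in features if f.triggered for k in f.implicated_residues}
    interface_set = _interface_residue_set(
        complex_structure, params, implicated_chains or {variant.chain_id},
        complex_access=complex_access,
    )
    damaging_feats = []
    for f in features:
        if not f.triggered:
            continue
        n_interface = len(f.implicated_residues & interface_set)
        if n_interface >= params.min_interchain_residues:
            damaging_feats.append(f)

    if damaging_feats:
        verdict = "damaging"
        names = ", ".join(f.feature_id.value for f in damaging_feats)
        rationale = (
            f"{len(damaging_feats)} structural damage feature(s) affect two or "
            f"more interchain residues: {names}"
        )
    else:
        verdict = "neutral"
        n_trig = sum(1 for f in features if f.triggered)
        rationale = (
            "no structural damage feature detected" if n_trig == 0 else
            f"{n_trig} feature(s) triggered but none implicates two or more "
            "interface residues"
        )

    return Prediction(
        variant=variant,
        verdict=verdict,
        category=site_ann.category,
        rsa_monomer=site_ann.rsa_monomer,
        rsa_complex=site_ann.rsa_complex,
        partner_chains=tuple(sorted(site_ann.partner_chains)),
        features=features,
        rationale=rationale,
        mutant=mutant,
    )


def render_report(p: Prediction, format: str = "json") -> str:
    """Serialise a prediction: every catalogue feature, not just triggers.

    The JSON form is schema-versioned and deterministic (no timestamps),
    so repeated runs on the same input are byte-identical.
    """
    if format == "json":
        doc = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "catalogue_version": CATALOGUE_VERSION,
            "variant": {
                "chain": p.variant.chain_id,
                "seq_num": p.variant.seq_num,
                "icode": p.variant.icode,
                "wt": p.variant.wt_aa,
                "mut": p.variant.mut_aa,
            },
            "verdict": p.verdict,
            "interface_category": p.category.value,
            "rsa_monomer": round(p.rsa_monomer, 2),
            "rsa_complex": round(p.rsa_complex, 2),
            "partner_chains": list(p.partner_chains),
            "rationale": p.rationale,
            "features": [
                {
                    "feature_id": f.feature_id.value,
                    "triggered": f.triggered,
                    "applicable": f.applicable,
                    "implicated_residues": [
                        {"chain": k[0], "seq_num": k[1], "icode": k[2]}
                        for k in sorted(f.implicated_residues)
                    ],
                    "evidence": f.evidence,
                }
                for f in p.features
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"

    if format == "text":
        lines = [
            f"Variant {p.variant.chain_id}/{p.variant.wt_aa}{p.variant.seq_num}"
            f"{p.variant.icode}{p.variant.mut_aa}",
            f"Verdict: {p.verdict}",
            f"Interface category: {p.category.value} "
            f"(RSA monomer {p.rsa_monomer:.1f}%, complex {p.rsa_complex:.1f}%)",
            f"Partner chains: {', '.join(p.partner_chains) or '-'}",
            f"Rationale: {p.rationale}",
            "Features:",
        ]
        for f in p.features:
            status = "TRIGGERED" if f.triggered else ("ok" if f.applicable else "n/a")
            lines.append(f"  [{status:>9}] {f.feature_id.value}"
                         + (f" — {f.evidence}" if f.evidence else ""))
        return "\n".join(lines) + "\n"

    raise ValueError(f"unknown report format {format!r}")
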