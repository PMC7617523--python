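"""Solvent accessibility: per-atom SASA and per-residue relative accessibility.

SASA is computed with the Shrake-Rupley sphere-sampling scheme on a
deterministic Fibonacci lattice, so results are bit-reproducible. RSA is
the residue SASA normalised by the theoretical maximum accessible area of
its residue type (Tien et al. scale), in percent. RSA may exceed 100% for
very extended conformations and is deliberately not clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chem import MAX_ASA
from .geometry import golden_spiral_points
from .structure_model import ResidueKey, Structure

__all__ = ["SasaParams", "ResidueAccessibility", "compute_sasa", "compute_rsa", "accessibility_table"]


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4  # Å, water probe
    n_sphere_points: int = 960

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 100:
            raise ValueError("n_sphere_points must be >= 100")


@dataclass
class ResidueAccessibility:
    residue_key: ResidueKey
    res_name: str
    sasa: float  # Å²
    rsa: float | None  # percent; None for non-standard residues
    context: str = ""  # "monomer" | "complex" | free label


def atom_sasa(coords: np.ndarray, radii: np.ndarray, params: SasaParams = SasaParams()) -> np.ndarray:
    """Shrake-Rupley SASA (Å²) for each atom in an arbitrary atom set."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    radii = np.asarray(radii, float)
    n = len(coords)
    expanded = radii + params.probe_radius
    sphere = golden_spiral_points(params.n_sphere_points)
    out = np.empty(n)

    tree = cKDTree(coords)
    max_r = expanded.max() if n else 0.0
    for i in range(n):
        r_i = expanded[i]
        # any sphere that can bury a surface point of atom i is within r_i + r_j
        neigh = [j for j in tree.query_ball_point(coords[i], r_i + max_r) if j != i]
        pts = coords[i] + r_i * sphere
        if neigh:
            nc = coords[neigh]
            nr = expanded[neigh]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < nr[None, :] ** 2).any(axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        out[i] = 4.0 * np.pi * r_i * r_i * exposed_frac
    return out


def compute_rsa(sasa: float, res_name: str) -> float:
    """Residue SASA as percent of the residue type's theoretical maximum."""
    if res_name not in MAX_ASA:
        raise KeyError(f"no max-ASA reference for residue type {res_name!r}")
    return 100.0 * sasa / MAX_ASA[res_name]


def compute_sasa(
    s: Structure,
    params: SasaParams = SasaParams(),
    context: str = "",
) -> dict[ResidueKey, ResidueAccessibility]:
    """Per-residue SASA and RSA for every residue of the structure.

    All chains present in ``s`` occlude one another, so calling this on a
    full assembly gives complex-context values and calling it on an
    extracted monomer gives monomer-context values.
    """
    pairs = s.all_atoms()
    if not pairs:
        raise ValueError("structure has no atoms")
    coords = np.array([a.coord for _, a in pairs], float)
    radii = np.array([a.vdw_radius for _, a in pairs], float)
    per_atom = atom_sasa(coords, radii, params)

    result: dict[ResidueKey, ResidueAccessibility] = {}
    totals: dict[ResidueKey, float] = {}
    names: dict[ResidueKey, str] = {}
    for (res, _), area in zip(pairs, per_atom):
        totals[res.key] = totals.get(res.key, 0.0) + float(area)
        names[res.key] = res.res_name
    for key, sasa in totals.items():
        name = names[key]
        if name in MAX_ASA:
            rsa = compute_rsa(sasa, name)
        else:
            rsa = None
            warnings.warn(
                f"residue {key} ({name}) has no RSA reference; "
                "excluded from interface analysis",
                stacklevel=2,
            )
        result[key] = ResidueAccessibility(key, name, sasa, rsa, context)
    return result


def accessibility_table(acc: dict[ResidueKey, ResidueAccessibility]) -> str:
    """TSV dump: chain, seq_num, icode, res_name, sasa, rsa, context."""
    lines = ["chain\tseq_num\ticode\tres_name\tsasa\trsa\tcontext"]
    for key in sorted(acc, key=lambda k: (k[0], k[1], k[2])):
        a = acc[key]
        rsa = f"{a.rsa:.2f}" if a.rsa is not None else "NA"
        lines.append(
            f"{key[0]}\t{key[1]}\t{key[2]}\t{a.res_name}\t{a.sasa:.2f}\t{rsa}\t{a.context}"
        )
    return "\n".join(lines) + "\n"
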