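"""Chemical reference tables.

Everything geometric downstream (SASA, bond detection, charge features,
side-chain building) reads from the tables in this module, so swapping a
radius set or an accessibility reference scale is a one-line change here.
"""

from __future__ import annotations

STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# Bondi van der Waals radii (Å) for the heavy elements found in proteins.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW = 1.70

# Theoretical maximum accessible surface areas (Å², Tien et al. scale).
# RSA = 100 * SASA / MAX_ASA[res_name].
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# Canonical side-chain heavy atoms per residue type (backbone excluded).
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

# Hydrogen-bond capable heavy atoms. Detection is distance-only (typical
# X-ray inputs carry no hydrogens), so donors and acceptors are named by
# heavy atom. Backbone N donates, backbone O accepts, for every residue.
HBOND_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
}
HBOND_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

# Side-chain atoms carrying a formal charge at physiological pH. Histidine
# is counted as positively charged because its protonation state cannot be
# inferred from heavy-atom coordinates.
POSITIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
NEGATIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
POSITIVE_AA = frozenset(POSITIVE_ATOMS)
NEGATIVE_AA = frozenset(NEGATIVE_ATOMS)
CHARGED_AA = POSITIVE_AA | NEGATIVE_AA


def formal_charge_sign(res_name: str) -> int:
    """+1 / -1 / 0 formal side-chain charge sign for a residue type."""
    if res_name in POSITIVE_AA:
        return 1
    if res_name in NEGATIVE_AA:
        return -1
    return 0


def element_of(atom_name: str) -> str:
    """Element symbol inferred from a PDB heavy-atom name."""
    for ch in atom_name:
        if ch.isalpha():
            return "S" if ch == "S" else ch
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element, DEFAULT_VDW)


# ---------------------------------------------------------------------------
# Side-chain internal-coordinate templates.
#
# Each entry places one heavy atom from three previously known atoms
# (a, b, c): bond length to c, angle b-c-X, torsion a-b-c-X. Torsions are
# either a fixed number of degrees or ("chi", k, offset) meaning the k-th
# variable chi angle plus a fixed offset. Values are ideal-geometry averages
# (Engh-Huber style); CB is placed first with the L-configuration torsion.
# ---------------------------------------------------------------------------

Torsion = float | tuple[str, int, float]
TemplateEntry = tuple[str, tuple[str, str, str], float, float, Torsion]

# L-configuration: improper torsion N-C-CA-CB is +120 degrees.
_CB: TemplateEntry = ("CB", ("N", "C", "CA"), 1.530, 110.1, 120.0)

SIDECHAIN_TEMPLATES: dict[str, list[TemplateEntry]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [
        _CB,
        ("OG1", ("N", "CA", "CB"), 1.433, 109.5, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.3, ("chi", 1, -120.0)),
    ],
    "VAL": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.527, 110.7, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.527, 110.4, ("chi", 1, 122.0)),
    ],
    "LEU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.5, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.5, ("chi", 2, 122.0)),
    ],
    "ILE": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "MET": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.8, ("chi", 3, 0.0)),
    ],
    "PRO": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.492, 104.5, 28.5),
        ("CD", ("CA", "CB", "CG"), 1.503, 105.5, -37.0),
    ],
    "PHE": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
    ],
    "TYR": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.512, 113.9, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
    ],
    "TRP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.433, 126.6, ("chi", 2, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
        ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0),
    ],
    "ASP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "ASN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 0.0)),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 180.0)),
    ],
    "GLN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.5, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.5, ("chi", 3, 0.0)),
        ("NZ", ("CG", "CD", "CE"), 1.489, 112.0, ("chi", 4, 0.0)),
    ],
    "ARG": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.8, ("chi", 2, 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 3, 0.0)),
        ("CZ", ("CG", "CD", "NE"), 1.329, 124.5, ("chi", 4, 0.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "HIS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 1, 0.0)),
        ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.356, 131.2, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.323, 109.0, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0),
    ],
}

# Compact backbone-independent rotamer library: every variable chi angle
# samples the three staggered wells, except aromatic/planar chi-2 which
# samples the perpendicular and in-plane orientations. Sizes stay under a
# hundred rotamers per residue type; the greedy packer scans all of them.
_STAGGERED = (-60.0, 180.0, 60.0)
_PLANAR2 = (90.0, -90.0, 180.0)

N_CHI = {
    "GLY": 0, "ALA": 0, "PRO": 0,
    "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "LEU": 2, "ILE": 2, "PHE": 2, "TYR": 2, "TRP": 2, "HIS": 2,
    "ASP": 2, "ASN": 2,
    "MET": 3, "GLU": 3, "GLN": 3,
    "LYS": 4, "ARG": 4,
}

_AROMATIC_CHI2 = frozenset({"PHE", "TYR", "TRP", "HIS", "ASP", "ASN"})


def rotamer_chi_sets(res_name: str) -> list[tuple[float, ...]]:
    """Enumerate candidate chi-angle combinations for one residue type."""
    n = N_CHI[res_name]
    if n == 0:
        return [()]
    rotamers: list[tuple[float, ...]] = [()]
    for k in range(1, n + 1):
        if k == 2 and res_name in _AROMATIC_CHI2:
            wells = _PLANAR2
        else:
            wells = _STAGGERED
        rotamers = [r + (w,) for r in rotamers for w in wells]
    return rotamers
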