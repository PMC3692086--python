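"""Chemical reference data for the 20 standard amino acids.

Everything geometric here is an *ideal* (Engh--Huber-style) template: bond
lengths in Angstrom, angles and torsions in degrees.  The bonded-energy
equilibrium values are taken from these same templates so that an ideally
built residue is strain free by construction.
"""

from __future__ import annotations

AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3_TO_1 = {v: k for k, v in AA1_TO_3.items()}

# Backbone ideal geometry (Engh & Huber style).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

# Improper dihedral C-N-CA-CB placing CB for an L-amino acid (negative in
# the IUPAC torsion convention; verified against crystal-structure geometry).
CB_IMPROPER = -122.6
ANGLE_N_CA_CB = 110.5
ANGLE_N_CA_CB_BY_RES = {"PRO": 103.0}
BOND_CA_CB = 1.530

# Side-chain heavy-atom templates.
# Entries: (atom, a, b, c, bond(c-atom), angle(b-c-atom), torsion(a-b-c-atom))
# torsion is a float or a string "chiK", "chiK+off", "chiK-off".
SIDECHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "ALA": [],
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, "chi1")],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 113.8, "chi1")],
    "THR": [("OG1", "N", "CA", "CB", 1.433, 109.6, "chi1"),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, "chi1-120.0")],
    "VAL": [("CG1", "N", "CA", "CB", 1.527, 110.4, "chi1"),
            ("CG2", "N", "CA", "CB", 1.527, 110.4, "chi1+120.0")],
    "ILE": [("CG1", "N", "CA", "CB", 1.530, 110.4, "chi1"),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, "chi1-120.0"),
            ("CD1", "CA", "CB", "CG1", 1.513, 113.8, "chi2")],
    "LEU": [("CG", "N", "CA", "CB", 1.530, 116.3, "chi1"),
            ("CD1", "CA", "CB", "CG", 1.521, 110.7, "chi2"),
            ("CD2", "CA", "CB", "CG", 1.521, 110.4, "chi2+122.6")],
    "ASP": [("CG", "N", "CA", "CB", 1.516, 112.6, "chi1"),
            ("OD1", "CA", "CB", "CG", 1.249, 118.4, "chi2"),
            ("OD2", "CA", "CB", "CG", 1.249, 118.4, "chi2+180")],
    "ASN": [("CG", "N", "CA", "CB", 1.516, 112.6, "chi1"),
            ("OD1", "CA", "CB", "CG", 1.231, 120.8, "chi2"),
            ("ND2", "CA", "CB", "CG", 1.328, 116.4, "chi2+180")],
    "GLU": [("CG", "N", "CA", "CB", 1.530, 114.1, "chi1"),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, "chi2"),
            ("OE1", "CB", "CG", "CD", 1.249, 118.4, "chi3"),
            ("OE2", "CB", "CG", "CD", 1.249, 118.4, "chi3+180")],
    "GLN": [("CG", "N", "CA", "CB", 1.530, 114.1, "chi1"),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, "chi2"),
            ("OE1", "CB", "CG", "CD", 1.231, 120.8, "chi3"),
            ("NE2", "CB", "CG", "CD", 1.328, 116.4, "chi3+180")],
    "MET": [("CG", "N", "CA", "CB", 1.530, 114.1, "chi1"),
            ("SD", "CA", "CB", "CG", 1.803, 112.7, "chi2"),
            ("CE", "CB", "CG", "SD", 1.791, 100.9, "chi3")],
    "LYS": [("CG", "N", "CA", "CB", 1.530, 114.1, "chi1"),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, "chi2"),
            ("CE", "CB", "CG", "CD", 1.508, 111.9, "chi3"),
            ("NZ", "CG", "CD", "CE", 1.489, 111.7, "chi4")],
    "ARG": [("CG", "N", "CA", "CB", 1.530, 114.1, "chi1"),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, "chi2"),
            ("NE", "CB", "CG", "CD", 1.461, 112.0, "chi3"),
            ("CZ", "CG", "CD", "NE", 1.329, 124.2, "chi4"),
            ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
            ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0)],
    "HIS": [("CG", "N", "CA", "CB", 1.497, 113.8, "chi1"),
            ("ND1", "CA", "CB", "CG", 1.378, 122.7, "chi2"),
            ("CD2", "CA", "CB", "CG", 1.354, 131.2, "chi2+180"),
            ("CE1", "CB", "CG", "ND1", 1.321, 109.3, 180.0),
            ("NE2", "CG", "ND1", "CE1", 1.374, 108.4, 0.0)],
    "PHE": [("CG", "N", "CA", "CB", 1.502, 113.8, "chi1"),
            ("CD1", "CA", "CB", "CG", 1.384, 120.7, "chi2"),
            ("CD2", "CA", "CB", "CG", 1.384, 120.7, "chi2+180"),
            ("CE1", "CB", "CG", "CD1", 1.382, 120.7, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.382, 120.7, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0)],
    "TYR": [("CG", "N", "CA", "CB", 1.502, 113.8, "chi1"),
            ("CD1", "CA", "CB", "CG", 1.384, 120.7, "chi2"),
            ("CD2", "CA", "CB", "CG", 1.384, 120.7, "chi2+180"),
            ("CE1", "CB", "CG", "CD1", 1.382, 120.7, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.382, 120.7, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0),
            ("OH", "CD1", "CE1", "CZ", 1.376, 119.9, 180.0)],
    "TRP": [("CG", "N", "CA", "CB", 1.498, 113.6, "chi1"),
            ("CD1", "CA", "CB", "CG", 1.365, 126.9, "chi2"),
            ("CD2", "CA", "CB", "CG", 1.433, 126.6, "chi2+180"),
            ("NE1", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
            ("CE2", "CG", "CD1", "NE1", 1.370, 108.9, 0.0),
            ("CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
            ("CZ2", "CD1", "NE1", "CE2", 1.394, 130.1, 180.0),
            ("CZ3", "CG", "CD2", "CE3", 1.382, 118.8, 180.0),
            ("CH2", "CD2", "CE3", "CZ3", 1.368, 121.1, 0.0)],
    "PRO": [("CG", "N", "CA", "CB", 1.492, 104.5, "chi1"),
            ("CD", "CA", "CB", "CG", 1.503, 105.5, "chi2")],
    "GLY": [],
}

# Ring/cycle closure bonds not implied by the template parent chain.
EXTRA_BONDS: dict[str, list[tuple[str, str]]] = {
    "HIS": [("CD2", "NE2")],
    "PHE": [("CE2", "CZ")],
    "TYR": [("CE2", "CZ")],
    "TRP": [("CD2", "CE2"), ("CZ2", "CH2")],
    "PRO": [("CD", "N")],
}

# chi torsion atom quadruples.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
}

CHI_COUNT = {res: len(v) for res, v in CHI_ATOMS.items()}

# Hydrogen counts per heavy atom; atoms absent from the map carry no H.
_BB_H = {"N": 1, "CA": 1}
H_COUNT: dict[str, dict[str, int]] = {
    "ALA": {**_BB_H, "CB": 3},
    "ARG": {**_BB_H, "CB": 2, "CG": 2, "CD": 2, "NE": 1, "NH1": 2, "NH2": 2},
    "ASN": {**_BB_H, "CB": 2, "ND2": 2},
    "ASP": {**_BB_H, "CB": 2},
    "CYS": {**_BB_H, "CB": 2, "SG": 1},
    "GLN": {**_BB_H, "CB": 2, "CG": 2, "NE2": 2},
    "GLU": {**_BB_H, "CB": 2, "CG": 2},
    "GLY": {"N": 1, "CA": 2},
    "HIS": {**_BB_H, "CB": 2, "CD2": 1, "CE1": 1, "NE2": 1},
    "ILE": {**_BB_H, "CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
    "LEU": {**_BB_H, "CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
    "LYS": {**_BB_H, "CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
    "MET": {**_BB_H, "CB": 2, "CG": 2, "CE": 3},
    "PHE": {**_BB_H, "CB": 2, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
    "PRO": {"CA": 1, "CB": 2, "CG": 2, "CD": 2},
    "SER": {**_BB_H, "CB": 2, "OG": 1},
    "THR": {**_BB_H, "CB": 1, "OG1": 1, "CG2": 3},
    "TRP": {**_BB_H, "CB": 2, "CD1": 1, "NE1": 1, "CE3": 1, "CZ2": 1,
            "CZ3": 1, "CH2": 1},
    "TYR": {**_BB_H, "CB": 2, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "OH": 1},
    "VAL": {**_BB_H, "CB": 1, "CG1": 3, "CG2": 3},
}

# sp2 heavy atoms (for in-plane hydrogen placement); backbone N and C are
# always sp2, listed per residue for the side chain only.
SP2_ATOMS: dict[str, set[str]] = {
    "ARG": {"NE", "CZ", "NH1", "NH2"},
    "ASN": {"CG", "ND2"},
    "ASP": {"CG"},
    "GLN": {"CD", "NE2"},
    "GLU": {"CD"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
}

H_BOND_LENGTH = {"C": 1.090, "N": 1.010, "O": 0.960, "S": 1.340}

ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

# van der Waals contact radii (Probe/MolProbity-style), Angstrom.
# Hydrogens on N/O/S (polar) use VDW_RADIUS_H_POLAR instead of "H".
VDW_RADIUS = {"C": 1.70, "N": 1.55, "O": 1.40, "S": 1.80, "H": 1.17}
VDW_RADIUS_H_POLAR = 1.00

# Lennard-Jones parameters per element: (rmin/2 in A, epsilon in kcal/mol).
LJ_PARAMS = {
    "C": (1.90, 0.086),
    "N": (1.80, 0.170),
    "O": (1.70, 0.210),
    "S": (2.00, 0.250),
    "H": (1.10, 0.022),
}

# Lazaridis--Karplus-style implicit-solvation parameters per element:
# (dG_ref kcal/mol, dG_free kcal/mol, volume A^3, correlation length A).
SOLVATION_PARAMS = {
    "C": (0.60, 0.60, 14.7, 3.5),
    "N": (-1.80, -1.80, 11.2, 3.5),
    "O": (-2.00, -2.00, 10.8, 3.5),
    "S": (-0.45, -0.45, 21.4, 3.5),
}

# Surface-tension-like coefficients (kcal/mol/A^2) for the smooth
# surface-area proxy term; positive favors burial of apolar atoms.
SASA_GAMMA = {"C": 0.012, "S": 0.010, "N": -0.005, "O": -0.005, "H": 0.0}
SASA_MAX_AREA = {"C": 36.0, "N": 30.0, "O": 29.0, "S": 41.0, "H": 15.0}

# Reduced partial-charge set (resname, atom) -> e.  Backbone charges are
# shared by all residues; atoms not listed are neutral.
BACKBONE_CHARGES = {"N": -0.47, "H": 0.31, "CA": 0.07, "HA": 0.09,
                    "HA1": 0.09, "HA2": 0.09, "C": 0.51, "O": -0.51}
SIDECHAIN_CHARGES: dict[str, dict[str, float]] = {
    "ASP": {"CB": -0.28, "CG": 0.62, "OD1": -0.76, "OD2": -0.76,
            "HB1": 0.09, "HB2": 0.09},
    "GLU": {"CG": -0.28, "CD": 0.62, "OE1": -0.76, "OE2": -0.76,
            "HG1": 0.09, "HG2": 0.09},
    "LYS": {"CE": 0.21, "HE1": 0.05, "HE2": 0.05, "NZ": -0.30,
            "HZ1": 0.33, "HZ2": 0.33, "HZ3": 0.33},
    "ARG": {"CD": 0.20, "HD1": 0.09, "HD2": 0.09, "NE": -0.70, "HE": 0.44,
            "CZ": 0.64, "NH1": -0.80, "NH2": -0.80,
            "HH11": 0.46, "HH12": 0.46, "HH21": 0.46, "HH22": 0.46},
    "SER": {"CB": 0.05, "HB1": 0.09, "HB2": 0.09, "OG": -0.66, "HG": 0.43},
    "THR": {"CB": 0.14, "HB": 0.09, "OG1": -0.66, "HG1": 0.43},
    "TYR": {"CZ": 0.11, "OH": -0.54, "HH": 0.43},
    "ASN": {"CG": 0.55, "OD1": -0.55, "ND2": -0.62, "HD21": 0.31,
            "HD22": 0.31},
    "GLN": {"CD": 0.55, "OE1": -0.55, "NE2": -0.62, "HE21": 0.31,
            "HE22": 0.31},
    "HIS": {"CG": 0.05, "ND1": -0.36, "CD2": 0.10, "CE1": 0.25,
            "NE2": -0.36, "HE2": 0.32},
    "TRP": {"NE1": -0.38, "HE1": 0.38},
    "CYS": {"CB": 0.07, "SG": -0.23, "HG": 0.16},
    "MET": {"CG": 0.045, "SD": -0.09, "CE": 0.045},
}

# Characteristic side-chain atom used by the side-chain distance metric
# (one atom per residue type, GLY excluded).
GDC_SC_ATOM = {
    "ALA": "CB", "ARG": "NH1", "ASN": "OD1", "ASP": "OD1", "CYS": "SG",
    "GLN": "OE1", "GLU": "OE1", "HIS": "NE2", "ILE": "CD1", "LEU": "CD1",
    "LYS": "NZ", "MET": "CE", "PHE": "CZ", "PRO": "CG", "SER": "OG",
    "THR": "OG1", "TRP": "CH2", "TYR": "OH", "VAL": "CG1",
}

# Kyte-Doolittle-style hydrophobicity (rescaled to roughly [0, 1]) used by
# the knowledge-based residue-pair potential.
HYDROPHOBICITY = {
    "ILE": 1.00, "VAL": 0.97, "LEU": 0.92, "PHE": 0.81, "CYS": 0.78,
    "MET": 0.71, "ALA": 0.70, "GLY": 0.46, "THR": 0.42, "SER": 0.41,
    "TRP": 0.40, "TYR": 0.36, "PRO": 0.32, "HIS": 0.14, "GLU": 0.11,
    "GLN": 0.11, "ASP": 0.11, "ASN": 0.11, "LYS": 0.07, "ARG": 0.00,
}


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB atom name."""
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name[1:]
    if name.startswith("H"):
        return "H"
    return name[0]


def heavy_atom_names(resname: str) -> list[str]:
    """Canonical heavy atoms of a residue, backbone first."""
    names = ["N", "CA", "C", "O"]
    if resname != "GLY":
        names.append("CB")
    names.extend(entry[0] for entry in SIDECHAIN_TEMPLATES[resname])
    return names


def residue_bonds(resname: str) -> list[tuple[str, str]]:
    """Heavy-atom bond list within one residue (no peptide link)."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    if resname != "GLY":
        bonds.append(("CA", "CB"))
    for entry in SIDECHAIN_TEMPLATES[resname]:
        bonds.append((entry[3], entry[0]))
    bonds.extend(EXTRA_BONDS.get(resname, []))
    return bonds


def hydrogen_names(resname: str, heavy: str) -> list[str]:
    """Deterministic hydrogen names for a heavy atom."""
    n = H_COUNT.get(resname, {}).get(heavy, 0)
    if n == 0:
        return []
    if heavy == "N":
        return ["H"]
    if heavy == "CA":
        return ["HA"] if n == 1 else ["HA1", "HA2"]
    suffix = heavy[1:]
    if n == 1 and heavy in ("CB", "OG", "OG1", "SG", "CG", "OH", "NE",
                            "NE1", "CD1", "CD2", "CE1", "CE2", "CE3",
                            "CZ", "CZ2", "CZ3", "CH2", "NE2"):
        return ["H" + suffix] if suffix else ["H"]
    return [f"H{suffix}{i + 1}" for i in range(n)] if n > 1 else ["H" + suffix]


def partial_charge(resname: str, atom_name: str) -> float:
    if atom_name in BACKBONE_CHARGES and not (
            resname == "PRO" and atom_name == "H"):
        return BACKBONE_CHARGES[atom_name]
    return SIDECHAIN_CHARGES.get(resname, {}).get(atom_name, 0.0)
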