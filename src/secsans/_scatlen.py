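"""Neutron coherent scattering lengths, displaced atomic volumes and
united-atom hydrogen counts for protein structures.

Scattering lengths are the standard tabulated bound coherent values (fm).
Displaced volumes are the per-atom solvent-excluded volumes commonly used in
solution-scattering codes; values for elements beyond H/C/N/O/S are nominal.
Hydrogen counts follow standard amino-acid topology at pH 7 (Asp/Glu
deprotonated, Lys/Arg protonated, His neutral with the NE2 tautomer); labile
hydrogens are those bonded to N, O or S.
"""

from __future__ import annotations

# bound coherent scattering length, fm
B_COH = {
    "H": -3.739,
    "D": 6.671,
    "C": 6.646,
    "N": 9.36,
    "O": 5.803,
    "S": 2.847,
    "P": 5.13,
    "SE": 7.97,
    "FE": 9.45,
    "ZN": 5.680,
    "MG": 5.375,
    "CA": 4.70,
    "MN": -3.73,
    "CU": 7.718,
    "NA": 3.63,
    "K": 3.67,
    "CL": 9.577,
}

# displaced (solvent-excluded) volume per atom, A^3
V_DISP = {
    "H": 5.15,
    "D": 5.15,
    "C": 16.44,
    "N": 2.49,
    "O": 9.13,
    "S": 19.86,
    "P": 5.73,
    "SE": 28.73,
    "FE": 7.99,
    "ZN": 9.85,
    "MG": 16.8,
    "CA": 31.9,
    "MN": 9.2,
    "CU": 8.78,
    "NA": 49.0,
    "K": 101.0,
    "CL": 28.8,
}

V_WATER = 30.0  # A^3 per water molecule
B_H2O = 2 * B_COH["H"] + B_COH["O"]
B_D2O = 2 * B_COH["D"] + B_COH["O"]


def solvent_sld(d2o_fraction: float) -> float:
    """Scattering length density (fm/A^3) of an H2O/D2O mixture."""
    if not (0.0 <= d2o_fraction <= 1.0):
        raise ValueError("d2o_fraction must lie in [0, 1]")
    return ((1.0 - d2o_fraction) * B_H2O + d2o_fraction * B_D2O) / V_WATER


# (n_hydrogens, n_labile) for backbone atoms; GLY CA and PRO N are special-cased
_BACKBONE = {"N": (1, 1), "CA": (1, 0), "C": (0, 0), "O": (0, 0), "OXT": (1, 1)}

# side-chain united-atom hydrogen counts keyed by residue, then atom name
_SIDECHAIN: dict[str, dict[str, tuple[int, int]]] = {
    "ALA": {"CB": (3, 0)},
    "ARG": {"CB": (2, 0), "CG": (2, 0), "CD": (2, 0), "NE": (1, 1), "CZ": (0, 0),
            "NH1": (2, 2), "NH2": (2, 2)},
    "ASN": {"CB": (2, 0), "CG": (0, 0), "OD1": (0, 0), "ND2": (2, 2)},
    "ASP": {"CB": (2, 0), "CG": (0, 0), "OD1": (0, 0), "OD2": (0, 0)},
    "CYS": {"CB": (2, 0), "SG": (1, 1)},
    "GLN": {"CB": (2, 0), "CG": (2, 0), "CD": (0, 0), "OE1": (0, 0), "NE2": (2, 2)},
    "GLU": {"CB": (2, 0), "CG": (2, 0), "CD": (0, 0), "OE1": (0, 0), "OE2": (0, 0)},
    "GLY": {},
    "HIS": {"CB": (2, 0), "CG": (0, 0), "ND1": (0, 0), "CD2": (1, 0), "CE1": (1, 0),
            "NE2": (1, 1)},
    "ILE": {"CB": (1, 0), "CG1": (2, 0), "CG2": (3, 0), "CD1": (3, 0)},
    "LEU": {"CB": (2, 0), "CG": (1, 0), "CD1": (3, 0), "CD2": (3, 0)},
    "LYS": {"CB": (2, 0), "CG": (2, 0), "CD": (2, 0), "CE": (2, 0), "NZ": (3, 3)},
    "MET": {"CB": (2, 0), "CG": (2, 0), "SD": (0, 0), "CE": (3, 0)},
    "PHE": {"CB": (2, 0), "CG": (0, 0), "CD1": (1, 0), "CD2": (1, 0), "CE1": (1, 0),
            "CE2": (1, 0), "CZ": (1, 0)},
    "PRO": {"CB": (2, 0), "CG": (2, 0), "CD": (2, 0)},
    "SER": {"CB": (2, 0), "OG": (1, 1)},
    "THR": {"CB": (1, 0), "OG1": (1, 1), "CG2": (3, 0)},
    "TRP": {"CB": (2, 0), "CG": (0, 0), "CD1": (1, 0), "CD2": (0, 0), "NE1": (1, 1),
            "CE2": (0, 0), "CE3": (1, 0), "CZ2": (1, 0), "CZ3": (1, 0), "CH2": (1, 0)},
    "TYR": {"CB": (2, 0), "CG": (0, 0), "CD1": (1, 0), "CD2": (1, 0), "CE1": (1, 0),
            "CE2": (1, 0), "CZ": (0, 0), "OH": (1, 1)},
    "VAL": {"CB": (1, 0), "CG1": (3, 0), "CG2": (3, 0)},
}


def hydrogen_counts(residue: str, atom_name: str) -> tuple[int, int]:
    """(implicit hydrogens, of which labile) for a heavy atom of a residue.

    Atoms outside the standard topology (ligands, waters, unknown residues)
    get no implicit hydrogens.
    """
    residue = residue.upper()
    atom_name = atom_name.upper()
    if atom_name in _BACKBONE:
        if atom_name == "CA" and residue == "GLY":
            return (2, 0)
        if atom_name == "N" and residue == "PRO":
            return (0, 0)
        return _BACKBONE[atom_name]
    return _SIDECHAIN.get(residue, {}).get(atom_name, (0, 0))
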