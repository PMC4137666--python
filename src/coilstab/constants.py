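"""Physical constants, residue tables and default cutoffs.

All lengths are in Angstrom, energies in kJ/mol, temperatures in Kelvin
and angles in degrees unless a name says otherwise.
"""

from __future__ import annotations

import importlib.resources

import numpy as np

#: Boltzmann constant, kJ/mol/K (simulation-engine convention).
KB = 0.0083144621

# ---------------------------------------------------------------------------
# Interaction cutoffs (geometric census defaults)
# ---------------------------------------------------------------------------

#: Donor-acceptor distance cutoff for hydrogen bonds, Angstrom (inclusive).
HBOND_DISTANCE_CUTOFF = 3.5
#: Deviation from linearity of the donor-H-acceptor angle, degrees (inclusive).
HBOND_ANGLE_CUTOFF = 30.0
#: Donor-acceptor atom distance cutoff for salt bridges, Angstrom (inclusive).
SALT_BRIDGE_CUTOFF = 4.0
#: Side-chain center-of-mass distance cutoff for hydrophobic contacts, Angstrom.
HYDROPHOBIC_CUTOFF = 7.0

#: Helix dihedral window: residue is helical iff phi/psi (where defined)
#: fall inside these closed intervals.
HELIX_PHI_RANGE = (-100.0, -30.0)
HELIX_PSI_RANGE = (-67.0, -7.0)

# ---------------------------------------------------------------------------
# Residues
# ---------------------------------------------------------------------------

AA1_TO_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3_TO_AA1 = {v: k for k, v in AA1_TO_AA3.items()}
STANDARD_AA = frozenset(AA1_TO_AA3)

#: Apolar set used for heptad-register scoring and hydrophobic contacts.
#: Conventional apolar residues; Gly, Pro and Tyr are excluded.
HYDROPHOBIC_SET = frozenset("AVLIMFW")

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Default side-chain pKa values for titratable groups. A group is
#: protonated iff pH < pKa (strict).
DEFAULT_PKA = {
    "ASP": 3.65,
    "GLU": 4.25,
    "HIS": 6.0,
    "LYS": 10.4,
    "ARG": 12.0,
    "CTERM": 3.6,
    "NTERM": 8.0,
}

#: Distance (Angstrom) from CA to the side-chain center of mass, used to
#: place the single side-chain pseudo-atom of built structures. Calibrated
#: per residue so the pseudo-atom stands for the side-chain COM.
SIDECHAIN_COM_DISTANCE = {
    "ALA": 1.53, "ARG": 4.10, "ASN": 2.47, "ASP": 2.47, "CYS": 2.07,
    "GLN": 3.09, "GLU": 3.11, "HIS": 3.14, "ILE": 2.30, "LEU": 2.61,
    "LYS": 3.50, "MET": 2.95, "PHE": 3.41, "PRO": 1.87, "SER": 1.90,
    "THR": 1.93, "TRP": 3.86, "TYR": 3.84, "VAL": 1.97,
}

#: Residues whose side chain carries a charged group; built structures give
#: these an extra charged-group pseudo-atom 2.5 A beyond the COM pseudo-atom.
CHARGED_RESIDUES = frozenset({"LYS", "ARG", "HIS", "ASP", "GLU"})
CHARGED_EXTENSION = 2.5

#: Atom names used for the side-chain pseudo-atoms of built structures.
SIDECHAIN_COM_ATOM = "SC"
CHARGED_GROUP_ATOM = "SQ"

BACKBONE_ATOMS = frozenset({"N", "H", "CA", "C", "O", "OXT"})


def reference_remd_ladder() -> np.ndarray:
    """The shipped 64-rung reference REMD temperature ladder (K)."""
    text = (
        importlib.resources.files("coilstab.data")
        .joinpath("remd_ladder.txt")
        .read_text()
    )
    values = [
        float(line) for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return np.asarray(values)
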