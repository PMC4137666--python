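import numpy as np
import pytest

from coilstab import CrickParameters, Structure, build_ideal_coiled_coil
from coilstab.sequences import LIC80_SYNTHETIC

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@pytest.fixture(scope="session")
def lic35():
    """Small built trimer reused across tests (35 residues, 3 chains)."""
    return build_ideal_coiled_coil(LIC80_SYNTHETIC[:35], CrickParameters())


@pytest.fixture(scope="session")
def lic80():
    return build_ideal_coiled_coil(LIC80_SYNTHETIC, CrickParameters())


def make_random_frame(rng, n_residues_per_chain, box=22.0):
    """A random pseudo-atom structure: 3 chains of residues with backbone
    N/H/CA/C/O and SC (+SQ for charged residues) at random coordinates
    inside a box (so cutoff-range pairs occur). Amide H atoms are placed
    1.0 A from N; a few donors are left without H on purpose."""
    letters = "ARNDCQEGHILKMFPSTWYV"
    names, chains, resids, resnames, coords = [], [], [], [], []
    for ci, chain in enumerate("ABC"):
        for r in range(1, n_residues_per_chain + 1):
            aa = letters[rng.integers(len(letters))]
            res3 = AA3[aa]
            n_xyz = rng.uniform(0, box, 3)
            atoms = [("N", n_xyz)]
            if rng.random() > 0.1:  # some amides deliberately lack H
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                atoms.append(("H", n_xyz + direction))
            atoms += [
                ("CA", rng.uniform(0, box, 3)),
                ("C", rng.uniform(0, box, 3)),
                ("O", rng.uniform(0, box, 3)),
            ]
            if r == n_residues_per_chain and rng.random() < 0.5:
                atoms.append(("OXT", rng.uniform(0, box, 3)))
            if res3 != "GLY":
                atoms.append(("SC", rng.uniform(0, box, 3)))
                if res3 in {"LYS", "ARG", "HIS", "ASP", "GLU"}:
                    atoms.append(("SQ", rng.uniform(0, box, 3)))
            for name, xyz in atoms:
                names.append(name)
                chains.append(chain)
                resids.append(r)
                resnames.append(res3)
                coords.append(xyz)
    return Structure(names, chains, resids, resnames, np.array(coords))
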