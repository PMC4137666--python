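"""Geometric interaction census.

Hydrogen bonds, salt bridges and hydrophobic contacts are detected with
purely geometric criteria:

* H-bond: donor-acceptor distance <= 3.5 A and deviation of the
  donor-H-acceptor angle from linearity <= 30 deg (both inclusive); one
  record per (donor-H, acceptor) pair.
* Salt bridge: closest basic-group / acidic-group atom pair <= 4.0 A, no
  angle test, one record per residue pair; intermonomer pairs only.
* Hydrophobic contact: side-chain centers of mass of two apolar residues
  on different chains <= 7.0 A apart; one record per residue pair.

Protonation gates participation: a protonated carboxylate is neither a
salt-bridge partner nor an H-bond acceptor, and histidine is a
salt-bridge donor only while its imidazole is protonated.

Helix content uses a dihedral-window criterion: a residue is helical iff
its defined backbone dihedrals fall in phi in [-100, -30] and psi in
[-67, -7] degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (
    BACKBONE_ATOMS,
    CHARGED_GROUP_ATOM,
    HBOND_ANGLE_CUTOFF,
    HBOND_DISTANCE_CUTOFF,
    HELIX_PHI_RANGE,
    HELIX_PSI_RANGE,
    HYDROPHOBIC_CUTOFF,
    HYDROPHOBIC_SET,
    SALT_BRIDGE_CUTOFF,
    SIDECHAIN_COM_ATOM,
    AA3_TO_AA1,
)
from .structure import Structure
from .vecmath import angle_deg, dihedral_deg

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "kind",
    "chain_i", "resid_i", "resname_i", "atom_i",
    "chain_j", "resid_j", "resname_j", "atom_j",
    "distance_A", "angle_deg", "iclass",
]

# side-chain donor heavy atoms (with their hydrogens attached) by residue
SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "ASN": ("ND2",), "GLN": ("NE2",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
    "TYR": ("OH",),
}
# side-chain acceptors; D/E entries are gated by protonation state
SIDECHAIN_ACCEPTORS = {
    "SER": ("OG", SIDECHAIN_COM_ATOM),
    "THR": ("OG1", SIDECHAIN_COM_ATOM),
    "ASN": ("OD1", SIDECHAIN_COM_ATOM),
    "GLN": ("OE1", SIDECHAIN_COM_ATOM),
    "HIS": ("ND1", "NE2"),
    "TYR": ("OH", SIDECHAIN_COM_ATOM),
    "ASP": ("OD1", "OD2", CHARGED_GROUP_ATOM),
    "GLU": ("OE1", "OE2", CHARGED_GROUP_ATOM),
}
CARBOXYL_RESIDUES = frozenset({"ASP", "GLU"})

BASIC_GROUP_ATOMS = {
    "LYS": ("NZ", CHARGED_GROUP_ATOM),
    "ARG": ("NE", "NH1", "NH2", CHARGED_GROUP_ATOM),
    "HIS": ("ND1", "NE2", CHARGED_GROUP_ATOM),  # only while protonated
}
ACIDIC_GROUP_ATOMS = {
    "ASP": ("OD1", "OD2", CHARGED_GROUP_ATOM),
    "GLU": ("OE1", "OE2", CHARGED_GROUP_ATOM),
}

_ATOM_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}


@dataclass
class InteractionSet:
    """Typed interaction records of one frame.

    ``records`` holds one row per contact with partner identities,
    geometry, and the class label (``intermonomer`` / ``intramonomer`` /
    ``mainchain``).
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=RECORD_COLUMNS)
    )

    def __len__(self) -> int:
        return len(self.records)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.records[self.records["kind"] == kind]

    def of_class(self, iclass: str) -> "InteractionSet":
        return InteractionSet(
            self.records[self.records["iclass"] == iclass].reset_index(drop=True)
        )

    @staticmethod
    def concat(sets) -> "InteractionSet":
        frames = [s.records for s in sets if len(s)]
        if not frames:
            return InteractionSet()
        return InteractionSet(pd.concat(frames, ignore_index=True))


def _classify(kind, chain_i, atom_i, chain_j, atom_j) -> str:
    if chain_i != chain_j:
        return "intermonomer"
    if kind == "hbond" and atom_i in BACKBONE_ATOMS and atom_j in BACKBONE_ATOMS:
        return "mainchain"
    return "intramonomer"


def _is_protonated(protonation, chain, resid) -> bool:
    if protonation is None:
        return False
    return protonation.is_sidechain_protonated(chain, resid)


def detect_hbonds(
    frame: Structure,
    d_max: float = HBOND_DISTANCE_CUTOFF,
    a_max: float = HBOND_ANGLE_CUTOFF,
    protonation=None,
    warn_missing_h: bool = True,
) -> InteractionSet:
    """All hydrogen bonds of one frame.

    Donors are backbone amides plus the side-chain donors of
    S/T/N/Q/K/R/H/Y; acceptors are backbone carbonyl oxygens plus the
    side-chain acceptors of S/T/N/Q/H/Y and of unprotonated D/E. A donor
    heavy atom with no hydrogen within bonding distance is skipped with a
    logged warning (side chains of pseudo-atom structures carry no
    hydrogens, so only their backbone donates).
    """
    res = frame.residue_table()
    names = frame.atom_names
    coords = frame.coords

    donors = []  # (heavy_idx, [h_idx, ...], res_row)
    acceptors = []  # (idx, res_row)
    skipped = 0
    for row in res.itertuples():
        sl = slice(row.start, row.stop)
        local = {}
        for j in range(row.start, row.stop):
            local.setdefault(names[j], j)
        h_atoms = [
            j for j in range(row.start, row.stop) if str(names[j]).startswith("H")
        ]
        donor_names = ["N"] + list(SIDECHAIN_DONORS.get(row.resname, ()))
        for dn in donor_names:
            if dn not in local:
                continue
            j = local[dn]
            hs = [
                h for h in h_atoms
                if np.linalg.norm(coords[h] - coords[j]) <= 1.25
            ]
            if not hs:
                skipped += 1
                continue
            donors.append((j, hs, row))

        acc_names = ["O", "OXT"]
        res_acc = SIDECHAIN_ACCEPTORS.get(row.resname, ())
        if row.resname in CARBOXYL_RESIDUES and _is_protonated(
            protonation, row.chain, row.resid
        ):
            res_acc = ()  # protonated carboxyl does not accept
        acc_names += list(res_acc)
        for an in acc_names:
            if an in local:
                acceptors.append((local[an], row))

    if skipped and warn_missing_h:
        logger.warning(
            "detect_hbonds: skipped %d donor group(s) with no attached hydrogen",
            skipped,
        )
    if not donors or not acceptors:
        return InteractionSet()

    acc_idx = np.array([a[0] for a in acceptors])
    tree = cKDTree(coords[acc_idx])
    rows = []
    for heavy, hs, drow in donors:
        for ai in tree.query_ball_point(coords[heavy], d_max):
            j, arow = acceptors[ai]
            if arow.chain == drow.chain and arow.resid == drow.resid:
                continue
            dist = float(np.linalg.norm(coords[j] - coords[heavy]))
            if dist > d_max:
                continue
            for h in hs:
                dev = 180.0 - float(angle_deg(coords[heavy], coords[h], coords[j]))
                if dev <= a_max:
                    rows.append(
                        (
                            "hbond",
                            drow.chain, drow.resid, drow.resname, names[heavy],
                            arow.chain, arow.resid, arow.resname, names[j],
                            dist, dev,
                            _classify("hbond", drow.chain, names[heavy], arow.chain, names[j]),
                        )
                    )
    return InteractionSet(pd.DataFrame(rows, columns=RECORD_COLUMNS))


def detect_salt_bridges(
    frame: Structure,
    protonation,
    d_max: float = SALT_BRIDGE_CUTOFF,
) -> InteractionSet:
    """Intermonomer salt bridges of one frame.

    A bridge links the charged group of K/R (always protonated at the pH
    range considered) or protonated H to an unprotonated D/E carboxylate
    (or a C-terminal carboxylate) on a different chain; the criterion is
    the closest inter-group atom distance, with no angle test. One record
    per residue pair.
    """
    res = frame.residue_table()
    names = frame.atom_names
    coords = frame.coords

    last_resid = {
        c: int(res[res["chain"] == c]["resid"].max()) for c in frame.chains
    }

    basic = []  # (res_row, [atom idx])
    acidic = []
    for row in res.itertuples():
        local = {}
        for j in range(row.start, row.stop):
            local.setdefault(names[j], []).append(j)
        if row.resname in BASIC_GROUP_ATOMS:
            if row.resname == "HIS" and not _is_protonated(
                protonation, row.chain, row.resid
            ):
                pass
            else:
                idx = [
                    j for an in BASIC_GROUP_ATOMS[row.resname]
                    for j in local.get(an, [])
                ]
                if idx:
                    basic.append((row, idx))
        if row.resname in ACIDIC_GROUP_ATOMS and not _is_protonated(
            protonation, row.chain, row.resid
        ):
            idx = [
                j for an in ACIDIC_GROUP_ATOMS[row.resname]
                for j in local.get(an, [])
            ]
            if idx:
                acidic.append((row, idx))
        # C-terminal carboxylate of each chain
        if row.resid == last_resid[row.chain] and "OXT" in local:
            if protonation is None or not protonation.cterm_protonated(row.chain):
                acidic.append((row, local["O"] + local["OXT"]))

    rows = []
    for brow, bidx in basic:
        for arow, aidx in acidic:
            if brow.chain == arow.chain:
                continue  # intermonomer interactions only
            d = np.linalg.norm(
                coords[np.asarray(bidx)][:, None, :] - coords[np.asarray(aidx)][None, :, :],
                axis=-1,
            )
            k = np.unravel_index(np.argmin(d), d.shape)
            if d[k] <= d_max:
                rows.append(
                    (
                        "saltbridge",
                        brow.chain, brow.resid, brow.resname, names[bidx[k[0]]],
                        arow.chain, arow.resid, arow.resname, names[aidx[k[1]]],
                        float(d[k]), np.nan, "intermonomer",
                    )
                )
    return InteractionSet(pd.DataFrame(rows, columns=RECORD_COLUMNS))


def sidechain_com(frame: Structure) -> pd.DataFrame:
    """Mass-weighted side-chain center of mass per residue (NaN for
    residues with no side-chain heavy atom, e.g. Gly)."""
    res = frame.residue_table()
    names = frame.atom_names
    out = []
    for row in res.itertuples():
        idx = [
            j for j in range(row.start, row.stop)
            if names[j] not in BACKBONE_ATOMS
            and not str(names[j]).startswith("H")
            and names[j] != CHARGED_GROUP_ATOM
        ]
        if idx:
            masses = np.array([_ATOM_MASS.get(str(names[j])[0], 12.011) for j in idx])
            com = (frame.coords[idx] * masses[:, None]).sum(axis=0) / masses.sum()
        else:
            com = np.full(3, np.nan)
        out.append((row.chain, row.resid, row.resname, *com))
    return pd.DataFrame(out, columns=["chain", "resid", "resname", "x", "y", "z"])


def detect_hydrophobic_contacts(
    frame: Structure,
    hydrophobic_set=HYDROPHOBIC_SET,
    d_max: float = HYDROPHOBIC_CUTOFF,
) -> InteractionSet:
    """Intermonomer hydrophobic contacts: one record per unordered pair
    of apolar residues on different chains whose side-chain centers of
    mass lie within ``d_max``."""
    com = sidechain_com(frame)
    sel = com[
        com["resname"].map(lambda r: AA3_TO_AA1.get(r, "X") in hydrophobic_set)
        & com["x"].notna()
    ].reset_index(drop=True)
    if len(sel) < 2:
        return InteractionSet()
    pts = sel[["x", "y", "z"]].to_numpy()
    tree = cKDTree(pts)
    rows = []
    for i, j in sorted(tree.query_pairs(d_max)):
        ri, rj = sel.iloc[i], sel.iloc[j]
        if ri["chain"] == rj["chain"]:
            continue
        dist = float(np.linalg.norm(pts[i] - pts[j]))
        rows.append(
            (
                "hydrophobic",
                ri["chain"], int(ri["resid"]), ri["resname"], SIDECHAIN_COM_ATOM,
                rj["chain"], int(rj["resid"]), rj["resname"], SIDECHAIN_COM_ATOM,
                dist, np.nan, "intermonomer",
            )
        )
    return InteractionSet(pd.DataFrame(rows, columns=RECORD_COLUMNS))


def count_sidechain_contacts_batch(
    coords: np.ndarray,
    atom_indices: np.ndarray,
    atom_chains: np.ndarray,
    d_max: float = HYDROPHOBIC_CUTOFF,
) -> np.ndarray:
    """Intermonomer contact counts for a whole coordinate stack at once.

    ``coords`` is (n_frames, n_atoms, 3); ``atom_indices`` selects one
    side-chain COM atom per participating residue with ``atom_chains``
    giving their chain labels. Counts unordered cross-chain pairs within
    ``d_max`` per frame — the batched equivalent of
    :func:`detect_hydrophobic_contacts` on single-pseudo-atom side
    chains (asserted equal in the test suite).
    """
    if len(atom_indices) == 0:
        return np.zeros(coords.shape[0], dtype=int)
    pts = coords[:, atom_indices]
    diff = pts[:, :, None, :] - pts[:, None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    inter = atom_chains[:, None] != atom_chains[None, :]
    iu = np.triu(np.ones_like(inter, dtype=bool), k=1)
    return np.sum((dist <= d_max) & (inter & iu), axis=(1, 2))


def hydrophobic_com_atoms(
    structure: Structure, hydrophobic_set=HYDROPHOBIC_SET
) -> tuple[np.ndarray, np.ndarray] | None:
    """Indices and chain labels of single side-chain COM pseudo-atoms of
    the apolar residues, or None when any apolar residue carries a
    multi-atom side chain (then the per-frame COM census must be used).
    """
    res = structure.residue_table()
    idx, chains = [], []
    for row in res.itertuples():
        if AA3_TO_AA1.get(row.resname, "X") not in hydrophobic_set:
            continue
        side = [
            j for j in range(row.start, row.stop)
            if structure.atom_names[j] not in BACKBONE_ATOMS
            and not str(structure.atom_names[j]).startswith("H")
            and structure.atom_names[j] != CHARGED_GROUP_ATOM
        ]
        if not side:
            continue
        if len(side) > 1 or structure.atom_names[side[0]] != SIDECHAIN_COM_ATOM:
            return None
        idx.append(side[0])
        chains.append(row.chain)
    return np.asarray(idx, dtype=int), np.asarray(chains, dtype=object)


def classify_and_count(iset: InteractionSet) -> dict[tuple[str, str], int]:
    """Counts per (kind, class). Classes partition the records, so the
    sum over classes equals the record count of each kind."""
    out: dict[tuple[str, str], int] = {}
    if len(iset):
        grouped = iset.records.groupby(["kind", "iclass"]).size()
        for (kind, iclass), n in grouped.items():
            out[(kind, iclass)] = int(n)
    return out


# ---------------------------------------------------------------------------
# Helix content
# ---------------------------------------------------------------------------

@dataclass
class HelixAssignment:
    """Per-residue helicity flags and the chain-averaged helix content."""

    flags: pd.DataFrame  # chain, resid, resname, helical
    content_pct: float
    per_chain: dict[str, float]


def helix_flags_from_backbone(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Helicity flags for chains given their backbone coordinate arrays
    of shape (..., L, 3); broadcasts over leading (frame) axes.

    A residue is helical iff every dihedral it has falls inside the
    helix window; chain-terminal residues are judged by their single
    defined dihedral.
    """
    L = N.shape[-2]
    if L < 3:
        raise ValueError("helix content needs chains of length >= 3")
    phi = dihedral_deg(C[..., :-1, :], N[..., 1:, :], CA[..., 1:, :], C[..., 1:, :])
    psi = dihedral_deg(N[..., :-1, :], CA[..., :-1, :], C[..., :-1, :], N[..., 1:, :])
    ok_phi = (phi >= HELIX_PHI_RANGE[0]) & (phi <= HELIX_PHI_RANGE[1])
    ok_psi = (psi >= HELIX_PSI_RANGE[0]) & (psi <= HELIX_PSI_RANGE[1])
    flags = np.zeros(N.shape[:-1], dtype=bool)
    flags[..., 0] = ok_psi[..., 0]
    flags[..., -1] = ok_phi[..., -1]
    flags[..., 1:-1] = ok_phi[..., :-1] & ok_psi[..., 1:]
    return flags


def assign_helix(frame: Structure) -> HelixAssignment:
    """Per-residue helicity and helix content (%) of one frame, averaged
    over chains."""
    rows = []
    per_chain = {}
    for cid in frame.chains:
        ch = frame.chain(cid)
        res = ch.residue_table()
        if len(res) < 3:
            raise ValueError(f"chain {cid} too short for helix content (< 3 residues)")
        N = np.stack([ch.coords[ch.atom_mask("N") & (ch.resids == r)][0] for r in res["resid"]])
        CA = np.stack([ch.coords[ch.atom_mask("CA") & (ch.resids == r)][0] for r in res["resid"]])
        C = np.stack([ch.coords[ch.atom_mask("C") & (ch.resids == r)][0] for r in res["resid"]])
        flags = helix_flags_from_backbone(N, CA, C)
        per_chain[cid] = 100.0 * flags.mean()
        for r, f in zip(res.itertuples(), flags):
            rows.append((cid, r.resid, r.resname, bool(f)))
    content = float(np.mean(list(per_chain.values())))
    return HelixAssignment(
        pd.DataFrame(rows, columns=["chain", "resid", "resname", "helical"]),
        content,
        per_chain,
    )
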