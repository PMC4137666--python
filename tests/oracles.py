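"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the interaction rules, clustering algorithm
and optimal superposition with plain double loops / numeric search so
they share no code path with the package implementation.
"""

import numpy as np
from scipy.optimize import minimize

BACKBONE = {"N", "H", "CA", "C", "O", "OXT"}
HYDROPHOBIC3 = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP"}

DONORS = {
    None: ("N",),  # backbone, any residue
    "SER": ("OG",), "THR": ("OG1",), "ASN": ("ND2",), "GLN": ("NE2",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
    "TYR": ("OH",),
}
ACCEPTORS_ALWAYS = {
    None: ("O", "OXT"),
    "SER": ("OG", "SC"), "THR": ("OG1", "SC"), "ASN": ("OD1", "SC"),
    "GLN": ("OE1", "SC"), "HIS": ("ND1", "NE2"), "TYR": ("OH", "SC"),
}
ACCEPTORS_CARBOXYL = {"ASP": ("OD1", "OD2", "SQ"), "GLU": ("OE1", "OE2", "SQ")}

BASIC = {"LYS": ("NZ", "SQ"), "ARG": ("NE", "NH1", "NH2", "SQ"),
         "HIS": ("ND1", "NE2", "SQ")}
ACIDIC = {"ASP": ("OD1", "OD2", "SQ"), "GLU": ("OE1", "OE2", "SQ")}


def _residues(frame):
    keys = []
    members = {}
    for j in range(frame.n_atoms):
        key = (frame.chain_ids[j], int(frame.resids[j]), frame.resnames[j])
        if key not in members:
            members[key] = []
            keys.append(key)
        members[key].append(j)
    return keys, members


def brute_hbond_count(frame, d_max=3.5, a_max=30.0, protonation=None) -> int:
    keys, members = _residues(frame)
    coords = frame.coords
    names = frame.atom_names

    donor_hs = []  # (res_key, heavy_idx, [h idx])
    acceptor_atoms = []  # (res_key, idx)
    for key in keys:
        chain, resid, resname = key
        idx = members[key]
        local = {}
        for j in idx:
            local.setdefault(names[j], j)
        hs_all = [j for j in idx if str(names[j]).startswith("H")]
        for dn in DONORS[None] + DONORS.get(resname, ()):
            if dn in local:
                attached = [
                    h for h in hs_all
                    if np.linalg.norm(coords[h] - coords[local[dn]]) <= 1.25
                ]
                if attached:
                    donor_hs.append((key, local[dn], attached))
        acc = ACCEPTORS_ALWAYS[None] + ACCEPTORS_ALWAYS.get(resname, ())
        if resname in ACCEPTORS_CARBOXYL:
            prot = protonation is not None and protonation.is_sidechain_protonated(
                chain, resid
            )
            if not prot:
                acc = acc + ACCEPTORS_CARBOXYL[resname]
        for an in acc:
            if an in local:
                acceptor_atoms.append((key, local[an]))

    count = 0
    for dkey, heavy, hs in donor_hs:
        for akey, aj in acceptor_atoms:
            if dkey[:2] == akey[:2]:
                continue
            d = np.linalg.norm(coords[aj] - coords[heavy])
            if d > d_max:
                continue
            for h in hs:
                v1 = coords[heavy] - coords[h]
                v2 = coords[aj] - coords[h]
                cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
                if 180.0 - ang <= a_max:
                    count += 1
    return count


def brute_salt_bridge_count(frame, protonation, d_max=4.0) -> int:
    keys, members = _residues(frame)
    coords = frame.coords
    names = frame.atom_names
    last = {}
    for chain, resid, _ in keys:
        last[chain] = max(last.get(chain, 0), resid)

    basic, acidic = [], []
    for key in keys:
        chain, resid, resname = key
        idx = members[key]
        local = {}
        for j in idx:
            local.setdefault(names[j], []).append(j)
        if resname in BASIC:
            if resname != "HIS" or (
                protonation is not None
                and protonation.is_sidechain_protonated(chain, resid)
            ):
                atoms = [j for an in BASIC[resname] for j in local.get(an, [])]
                if atoms:
                    basic.append((key, atoms))
        if resname in ACIDIC and not (
            protonation is not None
            and protonation.is_sidechain_protonated(chain, resid)
        ):
            atoms = [j for an in ACIDIC[resname] for j in local.get(an, [])]
            if atoms:
                acidic.append((key, atoms))
        if resid == last[chain] and "OXT" in local:
            if protonation is None or not protonation.cterm_protonated(chain):
                acidic.append((key, local["O"] + local["OXT"]))

    count = 0
    for (bc, _, _), batoms in basic:
        for (ac, _, _), aatoms in acidic:
            if bc == ac:
                continue
            dmin = min(
                np.linalg.norm(coords[i] - coords[j])
                for i in batoms
                for j in aatoms
            )
            if dmin <= d_max:
                count += 1
    return count


def brute_hydrophobic_count(frame, d_max=7.0) -> int:
    keys, members = _residues(frame)
    names = frame.atom_names
    masses = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
    coms = []
    for key in keys:
        chain, resid, resname = key
        if resname not in HYDROPHOBIC3:
            continue
        side = [
            j for j in members[key]
            if names[j] not in BACKBONE
            and not str(names[j]).startswith("H")
            and names[j] != "SQ"
        ]
        if not side:
            continue
        w = np.array([masses.get(str(names[j])[0], 12.011) for j in side])
        com = (frame.coords[side] * w[:, None]).sum(axis=0) / w.sum()
        coms.append((chain, com))
    count = 0
    for i in range(len(coms)):
        for j in range(i + 1, len(coms)):
            if coms[i][0] == coms[j][0]:
                continue
            if np.linalg.norm(coms[i][1] - coms[j][1]) <= d_max:
                count += 1
    return count


def brute_cluster(dist, energies_rank, cutoff):
    """Exhaustive largest-neighbor-count clustering on a distance matrix.

    ``energies_rank[i]`` orders models by energy (0 = lowest). Returns
    the list of (center, sorted members).
    """
    n = dist.shape[0]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best_center, best_count = None, -1
        for i in sorted(unassigned):
            c = sum(
                1
                for j in unassigned
                if j != i and dist[i, j] <= cutoff
            )
            if c > best_count or (
                c == best_count and energies_rank[i] < energies_rank[best_center]
            ):
                best_center, best_count = i, c
        members = [best_center] + [
            j for j in sorted(unassigned)
            if j != best_center and dist[best_center, j] <= cutoff
        ]
        clusters.append((best_center, sorted(members)))
        unassigned -= set(members)
    return clusters


def brute_superpose_rmsd(mobile, reference, n_starts=60, seed=0) -> float:
    """Best-RMSD rigid superposition found by numeric minimization over
    quaternions from many random starts (independent of any closed-form
    solution)."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)

    def rot(q):
        q = q / np.linalg.norm(q)
        w, x, y, z = q
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )

    def cost(q):
        return np.sqrt(np.mean(np.sum((P @ rot(q).T - Q) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        q0 = rng.normal(size=4)
        res = minimize(cost, q0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return float(best)
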