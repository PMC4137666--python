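"""Synthetic structure generation.

Three generators stand in for the modelling and simulation stages that a
full study would run with a folding engine and replica-exchange MD:

* :func:`build_ideal_coiled_coil` — an ideal parallel n-helix coiled coil
  from Crick parameters (supercoil radius/frequency, minor-helix
  radius/frequency, rise), with backbone N, H, CA, C, O atoms and one
  side-chain center-of-mass pseudo-atom per residue (plus a charged-group
  pseudo-atom for K/R/H/D/E).
* :func:`generate_replica_ensembles` — temperature-laddered ensembles with
  two-state loss of chain association and per-residue helicity, and
  Boltzmann-like per-frame pseudo-energies.
* :func:`generate_toy_thermo_samples` — exact Boltzmann samples of a 1-D
  harmonic well or a two-level system, the oracle inputs for histogram
  reweighting validation.

Geometry notes: the minor helix is realized by building a straight
alpha-helical backbone from ideal internal coordinates, measuring its
screw parameters, rescaling to the requested (R1, w1, rise), and bending
the result onto the supercoil path with the requested radius and
frequency. Chains of the bundle are exact rotated copies, so the built
structure has exact cyclic symmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import (
    AA1_TO_AA3,
    CHARGED_EXTENSION,
    CHARGED_GROUP_ATOM,
    CHARGED_RESIDUES,
    HYDROPHOBIC_SET,
    KB,
    SIDECHAIN_COM_ATOM,
    SIDECHAIN_COM_DISTANCE,
    STANDARD_AA,
)
from .structure import Ensemble, ReplicaSeries, Structure
from .vecmath import dihedral_deg, kabsch, nerf_place, principal_axis, unit

logger = logging.getLogger(__name__)

# Ideal backbone internal coordinates (Engh-Huber-like values).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.5
OMEGA = 180.0
#: Ideal alpha-helical backbone dihedrals used for the straight template.
HELIX_PHI = -57.8
HELIX_PSI = -47.0

#: Default supercoil pitch (Angstrom) used to derive w0 from R0.
DEFAULT_PITCH = 140.0

#: Coil-state dihedral ranges sampled by the replica generator (degrees).
COIL_PHI_RANGE = (-180.0, -30.0)
COIL_PSI_RANGE = (60.0, 180.0)
#: A chain-terminal residue is judged by phi alone, so its coil phi is
#: drawn from the sub-range disjoint from the helical window.
COIL_PHI_RANGE_TERMINAL = (-180.0, -100.0)
COIL_JITTER = 0.5


def _w0_from_pitch(r0: float, rise: float, pitch: float = DEFAULT_PITCH) -> float:
    """Supercoil frequency (deg/residue, negative = left-handed) for a
    supercoil of radius ``r0`` and pitch ``pitch``."""
    k = pitch / (2.0 * np.pi)
    return -float(np.degrees(rise / np.hypot(r0, k)))


@dataclass(frozen=True)
class CrickParameters:
    """Idealized coiled-coil geometry.

    ``supercoil_frequency_w0`` defaults to the left-handed frequency
    implied by ``supercoil_radius_r0`` and a pitch of 140 A; set it to 0
    for straight parallel helices.
    """

    supercoil_radius_r0: float = 6.1
    helix_radius_r1: float = 2.26
    supercoil_frequency_w0: float | None = None
    helix_frequency_w1: float = 102.857
    rise_per_residue: float = 1.51
    symmetry_order: int = 3
    registry_offset: int = 0

    def __post_init__(self):
        if self.supercoil_radius_r0 <= 0:
            raise ValueError("supercoil radius R0 must be positive")
        if self.helix_radius_r1 <= 0:
            raise ValueError("helix radius R1 must be positive")
        if self.symmetry_order < 2:
            raise ValueError("symmetry order must be >= 2")
        if not 0 <= int(self.registry_offset) <= 6:
            raise ValueError("registry offset must be in [0, 6]")
        if self.supercoil_frequency_w0 is None:
            object.__setattr__(
                self,
                "supercoil_frequency_w0",
                _w0_from_pitch(self.supercoil_radius_r0, self.rise_per_residue),
            )
        w0 = abs(np.radians(self.supercoil_frequency_w0))
        if w0 > 0 and self.rise_per_residue / w0 <= self.supercoil_radius_r0:
            raise ValueError("supercoil frequency too large for this radius")

    @classmethod
    def from_pitch(cls, r0: float, pitch: float = DEFAULT_PITCH, **kw):
        rise = kw.get("rise_per_residue", 1.51)
        return cls(
            supercoil_radius_r0=r0,
            supercoil_frequency_w0=_w0_from_pitch(r0, rise, pitch),
            **kw,
        )


# ---------------------------------------------------------------------------
# Straight-helix template
# ---------------------------------------------------------------------------

def _straight_template(n: int = 12):
    """Backbone N/CA/C/O coordinates of an ideal straight alpha helix of
    ``n`` residues, built by sequential internal-coordinate placement."""
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = nerf_place(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, HELIX_PSI)
        CA[i] = nerf_place(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = nerf_place(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, HELIX_PHI)
    O = nerf_place(N, CA, C, BOND_C_O, ANGLE_CA_C_O, HELIX_PSI + 180.0)
    return N, CA, C, O


def _screw_parameters(N, CA, C, O):
    """Axis frame, twist (deg/residue) and rise (A/residue) of the screw
    relating consecutive residues of an ideal helix."""
    i = len(N) // 2
    src = np.stack([N[i], CA[i], C[i], O[i]])
    dst = np.stack([N[i + 1], CA[i + 1], C[i + 1], O[i + 1]])
    R, t, _ = kabsch(src, dst)
    w, v = np.linalg.eig(R)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis = axis / np.linalg.norm(axis)
    cos_t = (np.trace(R) - 1.0) / 2.0
    twist = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    # orient axis so the screw is right-handed with positive rise
    sin_vec = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if sin_vec @ axis < 0:
        axis = -axis
    rise = float(t @ axis)
    if rise < 0:
        axis, rise = -axis, -rise
        sign = np.sign(sin_vec @ axis)
        twist = float(twist * (1 if sign >= 0 else -1))
    # a point on the axis: solve (I - R) p = t_perp in the axis-normal plane
    t_perp = t - (t @ axis) * axis
    p = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)[0]
    p = p - (p @ axis) * axis
    return axis, p, float(twist), rise


def _cylindrical_offsets(points, axis, origin, twist, rise):
    """Per-atom (radius, phase offset, z offset) of helix atoms relative
    to residue index, about the fitted screw axis."""
    e1 = unit(np.array([1.0, 0.0, 0.0]) - axis[0] * axis)
    if np.linalg.norm(np.array([1.0, 0.0, 0.0]) - axis[0] * axis) < 1e-6:
        e1 = unit(np.array([0.0, 1.0, 0.0]) - axis[1] * axis)
    e2 = np.cross(axis, e1)
    out = []
    for i, x in enumerate(points):
        rel = x - origin
        z = rel @ axis
        vx, vy = rel @ e1, rel @ e2
        r = np.hypot(vx, vy)
        phase = np.degrees(np.arctan2(vy, vx))
        out.append((r, phase - twist * i, z - rise * i))
    r, dphi, dz = np.array(out).T
    # offsets are constant along an ideal helix; average for robustness
    dphi = np.degrees(np.angle(np.mean(np.exp(1j * np.radians(dphi)))))
    return float(np.mean(r)), float(dphi), float(np.mean(dz))


def _minor_helix_offsets():
    """Cylindrical offsets of N, CA, C, O about the minor-helix axis of
    the ideal straight template (cached)."""
    global _OFFSET_CACHE
    try:
        return _OFFSET_CACHE
    except NameError:
        pass
    N, CA, C, O = _straight_template()
    axis, origin, twist, rise = _screw_parameters(N, CA, C, O)
    # side-chain direction reference points, for register phasing
    CB = np.stack(
        [CA[i] + 1.5 * _sidechain_direction(N[i], CA[i], C[i]) for i in range(len(N))]
    )
    sl = slice(3, 9)  # interior residues only
    offs = {
        name: _cylindrical_offsets(arr[sl], axis, origin, twist, rise)
        for name, arr in (
            ("N", N[sl]), ("CA", CA[sl]), ("C", C[sl]), ("O", O[sl]), ("CB", CB[sl])
        )
    }
    # fix residue-index offset introduced by slicing
    offs = {
        name: (r, dphi - twist * sl.start, dz - rise * sl.start)
        for name, (r, dphi, dz) in offs.items()
    }
    _OFFSET_CACHE = (offs, twist, rise)
    return _OFFSET_CACHE


def _straight_backbone(n_res: int, params: CrickParameters):
    """N/CA/C/O coordinates of a straight helix with the requested minor
    helix radius, frequency and rise, axis along +z."""
    offs, twist0, _ = _minor_helix_offsets()
    scale = params.helix_radius_r1 / offs["CA"][0]
    w1 = params.helix_frequency_w1
    rise = params.rise_per_residue
    # Phase the register so the side chains of the core positions a and d
    # straddle the inward direction (local phase 180 deg): residue i0 sits
    # at heptad position 'a' for the requested registry offset.
    i0 = (7 - params.registry_offset) % 7
    phase0 = 180.0 + 360.0 / 14.0 - offs["CB"][1] - w1 * i0
    i = np.arange(n_res)[:, None]
    coords = {}
    for name, (r, dphi, dz) in offs.items():
        if name == "CB":
            continue
        phi = np.radians(w1 * i + dphi + phase0)
        coords[name] = np.concatenate(
            [r * scale * np.cos(phi), r * scale * np.sin(phi), rise * i + dz],
            axis=1,
        )
    return coords


def _wrap_on_supercoil(xyz: np.ndarray, params: CrickParameters) -> np.ndarray:
    """Bend straight-helix coordinates (axis = z at the origin) onto the
    supercoil path; arc length along the path equals the straight z."""
    r0 = params.supercoil_radius_r0
    w0 = np.radians(params.supercoil_frequency_w0)
    x, y, s = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    if w0 == 0.0:
        return np.stack([r0 + x, y, s], axis=-1)
    a = params.rise_per_residue / abs(w0)
    k = np.sqrt(a * a - r0 * r0)
    sgn = np.sign(w0)
    theta = sgn * s / a
    ct, st = np.cos(theta), np.sin(theta)
    cx = r0 * ct
    cy = r0 * st
    cz = (k / a) * s
    # path frame: outward radial e_r, unit tangent T, binormal B = T x e_r
    tx, ty, tz = -r0 * st * sgn / a, r0 * ct * sgn / a, k / a
    bx = -(k / a) * st
    by = (k / a) * ct
    bz = -r0 * sgn / a
    return np.stack(
        [
            cx + x * ct + y * bx,
            cy + x * st + y * by,
            cz + y * bz,
        ],
        axis=-1,
    )


def _sidechain_direction(n, ca, c):
    """Unit vector from CA toward the idealized beta-carbon direction."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    d = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc
    return unit(d)


def build_ideal_coiled_coil(sequence: str, params: CrickParameters | None = None) -> Structure:
    """Build an ideal parallel coiled coil of ``params.symmetry_order``
    chains with the given sequence.

    Each residue carries backbone N, H, CA, C, O (no H on prolines or the
    chain-initial residue), one side-chain COM pseudo-atom (``SC``, absent
    for Gly) and, for charged residues, a charged-group pseudo-atom
    (``SQ``). Chains are exact rotated copies about the supercoil axis
    (+z), labelled A, B, C, ...
    """
    params = params or CrickParameters()
    sequence = str(sequence).upper().strip()
    if len(sequence) < 7:
        raise ValueError("sequence must contain at least one heptad (7 residues)")
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue letter(s): {sorted(bad)}")

    n_res = len(sequence)
    straight = _straight_backbone(n_res, params)
    bb = {name: _wrap_on_supercoil(arr, params) for name, arr in straight.items()}

    names, chains, resids, resnames, coords = [], [], [], [], []
    resnames3 = [AA1_TO_AA3[c] for c in sequence]
    for i in range(n_res):
        res3 = resnames3[i]
        atoms = [("N", bb["N"][i]), ("CA", bb["CA"][i]), ("C", bb["C"][i]), ("O", bb["O"][i])]
        if res3 != "GLY":
            d = _sidechain_direction(bb["N"][i], bb["CA"][i], bb["C"][i])
            sc = bb["CA"][i] + SIDECHAIN_COM_DISTANCE[res3] * d
            atoms.append((SIDECHAIN_COM_ATOM, sc))
            if res3 in CHARGED_RESIDUES:
                atoms.append((CHARGED_GROUP_ATOM, sc + CHARGED_EXTENSION * d))
        for name, xyz in atoms:
            names.append(name)
            chains.append("A")
            resids.append(i + 1)
            resnames.append(res3)
            coords.append(xyz)

    chain_a = Structure(names, chains, resids, resnames, np.array(coords))
    chain_a = place_amide_hydrogens(chain_a)

    parts = [chain_a]
    for j in range(1, params.symmetry_order):
        ang = 2.0 * np.pi * j / params.symmetry_order
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        cid = chr(ord("A") + j)
        parts.append(
            Structure(
                chain_a.atom_names,
                np.full(chain_a.n_atoms, cid, dtype=object),
                chain_a.resids,
                chain_a.resnames,
                chain_a.coords @ rot.T,
            )
        )
    return Structure(
        np.concatenate([p.atom_names for p in parts]),
        np.concatenate([p.chain_ids for p in parts]),
        np.concatenate([p.resids for p in parts]),
        np.concatenate([p.resnames for p in parts]),
        np.concatenate([p.coords for p in parts]),
    )


def place_amide_hydrogens(structure: Structure) -> Structure:
    """Return a copy with backbone amide hydrogens placed.

    H sits 1.00 A from N, in the C(i-1)-N(i)-CA(i) plane, opposite the
    bisector of that angle. Prolines and chain-initial residues receive
    no amide hydrogen; any pre-existing amide H atoms are replaced.
    """
    res = structure.residue_table()
    keep = ~structure.atom_mask("H")
    base = structure.select(keep)
    res_b = base.residue_table()

    names, chains, resids, resnames, coords = [], [], [], [], []
    prev_c: np.ndarray | None = None
    prev_chain = None
    for row in res_b.itertuples():
        sl = slice(row.start, row.stop)
        a_names = list(base.atom_names[sl])
        a_coords = base.coords[sl]
        try:
            n_xyz = a_coords[a_names.index("N")]
            ca_xyz = a_coords[a_names.index("CA")]
            c_xyz = a_coords[a_names.index("C")]
        except ValueError as exc:
            raise ValueError(
                f"residue {row.chain}/{row.resid} is missing backbone atoms"
            ) from exc

        emit = list(zip(a_names, a_coords))
        if prev_chain == row.chain and row.resname != "PRO":
            if prev_c is None:
                raise ValueError(
                    f"residue before {row.chain}/{row.resid} lacks a C atom"
                )
            h = n_xyz + 1.0 * unit(unit(n_xyz - prev_c) + unit(n_xyz - ca_xyz))
            i_n = a_names.index("N")
            emit = emit[: i_n + 1] + [("H", h)] + emit[i_n + 1:]
        for name, xyz in emit:
            names.append(name)
            chains.append(row.chain)
            resids.append(row.resid)
            resnames.append(row.resname)
            coords.append(xyz)
        prev_c = c_xyz
        prev_chain = row.chain
    del res
    return Structure(names, chains, resids, resnames, np.array(coords))


# ---------------------------------------------------------------------------
# Replica-ensemble generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltingModel:
    """Two-state melting parameters of the synthetic replica generator.

    Chain association and per-residue helicity each follow a logistic
    order parameter in temperature; the association midpoint must lie
    below the helix midpoint (contacts are lost before secondary
    structure). Energies are pseudo-energies in kJ/mol.
    """

    tm_association: float = 454.52
    tm_helix: float = 556.59
    width_association: float = 20.0
    width_helix: float = 15.0
    frames_per_temperature: int = 200
    seed: int = 0
    energy_scale_helix: float = 2.0
    energy_scale_contact: float = 4.0
    noise_sd: float = 5.0
    #: Radial displacement (A) of each chain in the dissociated state.
    separation_distance: float = 25.0

    def __post_init__(self):
        if self.width_association <= 0 or self.width_helix <= 0:
            raise ValueError("transition widths must be positive")
        if self.frames_per_temperature < 1:
            raise ValueError("frames_per_temperature must be >= 1")
        if not self.tm_association < self.tm_helix:
            raise ValueError(
                "tm_association must be below tm_helix (association is lost first)"
            )

    def p_helix(self, t: float) -> float:
        return 1.0 / (1.0 + np.exp((t - self.tm_helix) / self.width_helix))

    def p_associated(self, t: float) -> float:
        return 1.0 / (1.0 + np.exp((t - self.tm_association) / self.width_association))


class _ChainInternal:
    """Internal coordinates and atom-index maps of one folded chain."""

    def __init__(self, folded: Structure, chain_id: str):
        sub_mask = folded.chain_ids == chain_id
        idx_all = np.flatnonzero(sub_mask)
        res = folded.select(sub_mask).residue_table()
        L = len(res)
        self.length = L
        self.chain_id = chain_id

        def find(names_needed):
            out = {name: np.full(L, -1, dtype=int) for name in names_needed}
            for r, row in enumerate(res.itertuples()):
                for j in range(row.start, row.stop):
                    nm = folded.atom_names[idx_all[j]]
                    if nm in out:
                        out[nm][r] = idx_all[j]
            return out

        idx = find(["N", "CA", "C", "O", "H", SIDECHAIN_COM_ATOM, CHARGED_GROUP_ATOM])
        for nm in ("N", "CA", "C", "O"):
            if np.any(idx[nm] < 0):
                raise ValueError(
                    f"chain {chain_id}: every residue needs backbone {nm} atoms"
                )
        self.idx = idx
        self.resnames = list(res["resname"])

        X = folded.coords
        N, CA, C, O = (X[idx[nm]] for nm in ("N", "CA", "C", "O"))
        self.anchor = (N[0].copy(), CA[0].copy(), C[0].copy())

        from .vecmath import angle_deg

        self.bond_n = np.linalg.norm(N[1:] - C[:-1], axis=1)
        self.ang_n = angle_deg(CA[:-1], C[:-1], N[1:])
        self.bond_ca = np.linalg.norm(CA[1:] - N[1:], axis=1)
        self.ang_ca = angle_deg(C[:-1], N[1:], CA[1:])
        self.omega = dihedral_deg(CA[:-1], C[:-1], N[1:], CA[1:])
        self.bond_c = np.linalg.norm(C - CA, axis=1)[1:]
        self.ang_c = angle_deg(N, CA, C)[1:]
        self.phi = dihedral_deg(C[:-1], N[1:], CA[1:], C[1:])  # phi of residues 1..L-1
        self.psi = dihedral_deg(N[:-1], CA[:-1], C[:-1], N[1:])  # psi of residues 0..L-2

        self.bond_o = np.linalg.norm(O - C, axis=1)
        self.ang_o = angle_deg(CA, C, O)
        tor_o = dihedral_deg(N, CA, C, O)
        self.delta_o = np.empty(L)
        self.delta_o[:-1] = tor_o[:-1] - self.psi
        self.delta_o[-1] = tor_o[-1]  # absolute torsion for the last residue

        # side-chain pseudo-atoms in the local CA frame
        e1 = unit(N - CA)
        t = C - CA
        e2 = unit(t - np.sum(t * e1, axis=1, keepdims=True) * e1)
        e3 = np.cross(e1, e2)
        self.frame = (e1, e2, e3)
        self.sc_coeff = np.full((L, 3), np.nan)
        self.sq_coeff = np.full((L, 3), np.nan)
        for r in range(L):
            for nm, out in ((SIDECHAIN_COM_ATOM, self.sc_coeff), (CHARGED_GROUP_ATOM, self.sq_coeff)):
                j = idx[nm][r]
                if j >= 0:
                    rel = X[j] - CA[r]
                    out[r] = (rel @ e1[r], rel @ e2[r], rel @ e3[r])


def _rebuild_chains(ic: _ChainInternal, phi: np.ndarray, psi: np.ndarray):
    """Rebuild backbone coordinates of ``B`` copies of one chain from its
    stored internal coordinates with per-copy phi/psi overrides.

    ``phi``/``psi`` have shape (B, L); phi[:, 0] and psi[:, -1] are
    ignored (undefined dihedrals). Returns dict of (B, L, 3) arrays.
    """
    B, L = phi.shape
    N = np.empty((B, L, 3))
    CA = np.empty((B, L, 3))
    C = np.empty((B, L, 3))
    N[:, 0] = ic.anchor[0]
    CA[:, 0] = ic.anchor[1]
    C[:, 0] = ic.anchor[2]
    for i in range(1, L):
        N[:, i] = nerf_place(
            N[:, i - 1], CA[:, i - 1], C[:, i - 1],
            ic.bond_n[i - 1], ic.ang_n[i - 1], psi[:, i - 1],
        )
        CA[:, i] = nerf_place(
            CA[:, i - 1], C[:, i - 1], N[:, i],
            ic.bond_ca[i - 1], ic.ang_ca[i - 1], ic.omega[i - 1],
        )
        C[:, i] = nerf_place(
            C[:, i - 1], N[:, i], CA[:, i],
            ic.bond_c[i - 1], ic.ang_c[i - 1], phi[:, i],
        )
    tor_o = np.empty((B, L))
    tor_o[:, :-1] = psi[:, :-1] + ic.delta_o[:-1]
    tor_o[:, -1] = ic.delta_o[-1]
    O = nerf_place(N, CA, C, ic.bond_o, ic.ang_o, tor_o)
    return {"N": N, "CA": CA, "C": C, "O": O}


def _place_h_batch(bb: dict, resnames) -> np.ndarray:
    """Amide H for batched chains; NaN where no H exists (residue 1, Pro)."""
    N, CA, C = bb["N"], bb["CA"], bb["C"]
    B, L, _ = N.shape
    H = np.full((B, L, 3), np.nan)
    u = unit(N[:, 1:] - C[:, :-1])
    v = unit(N[:, 1:] - CA[:, 1:])
    H[:, 1:] = N[:, 1:] + unit(u + v)
    for r, res3 in enumerate(resnames):
        if res3 == "PRO":
            H[:, r] = np.nan
    return H


def _place_sidechains_batch(bb: dict, ic: _ChainInternal):
    N, CA, C = bb["N"], bb["CA"], bb["C"]
    e1 = unit(N - CA)
    t = C - CA
    e2 = unit(t - np.sum(t * e1, axis=-1, keepdims=True) * e1)
    e3 = np.cross(e1, e2)
    out = {}
    for nm, coeff in ((SIDECHAIN_COM_ATOM, ic.sc_coeff), (CHARGED_GROUP_ATOM, ic.sq_coeff)):
        out[nm] = (
            CA
            + coeff[:, 0, None] * e1
            + coeff[:, 1, None] * e2
            + coeff[:, 2, None] * e3
        )
    return out


def generate_replica_ensembles(
    folded: Structure,
    ladder,
    model: MeltingModel,
    hydrophobic_set=HYDROPHOBIC_SET,
) -> ReplicaSeries:
    """Generate independent per-temperature frame ensembles for a folded
    trimer (or n-mer) built by :func:`build_ideal_coiled_coil`.

    At temperature T each residue is independently helical with the
    logistic probability of :class:`MeltingModel`; non-helical residues
    are rebuilt with coil dihedrals and receive coordinate jitter on
    their non-dihedral-defining atoms (O, H, side-chain pseudo-atoms), so
    the realized secondary structure equals the sampled state exactly.
    Each frame is associated (chains at folded positions) or dissociated
    (chains displaced radially) by a Bernoulli draw of the association
    order parameter; the mean radial separation therefore grows with one
    minus that order parameter. Per-frame pseudo-energy is
    ``-e_helix * n_helical - e_contact * n_contacts + N(0, noise_sd)``.

    The same seed reproduces bit-identical output.
    """
    ladder = np.asarray(ladder, float)
    if ladder.ndim != 1 or len(ladder) < 1 or np.any(np.diff(ladder) <= 0):
        raise ValueError("temperature ladder must be strictly increasing")

    chains = folded.chains
    internals = [_ChainInternal(folded, c) for c in chains]
    n_res_total = sum(ic.length for ic in internals)

    # radial displacement directions from the folded supercoil axis
    ca_mask = folded.atom_mask("CA")
    centroid, axis = principal_axis(folded.coords[ca_mask])
    directions = []
    for c in chains:
        ccent = folded.chain(c).coords.mean(axis=0)
        rel = ccent - centroid
        rel = rel - (rel @ axis) * axis
        directions.append(unit(rel))

    # hydrophobic side-chain COM atoms for the contact bookkeeping
    from .constants import AA3_TO_AA1

    sc_all = np.flatnonzero(
        (folded.atom_names == SIDECHAIN_COM_ATOM)
        & np.fromiter(
            (AA3_TO_AA1.get(r, "X") in hydrophobic_set for r in folded.resnames),
            bool,
            folded.n_atoms,
        )
    )
    sc_chain = folded.chain_ids[sc_all]

    rng = np.random.default_rng(model.seed)
    B = model.frames_per_temperature
    ensembles: dict[float, Ensemble] = {}
    rows = []
    for t in ladder:
        p_h = model.p_helix(t)
        p_a = model.p_associated(t)
        coords = np.empty((B, folded.n_atoms, 3))
        n_helical = np.zeros(B, dtype=int)
        associated = rng.random(B) < p_a
        for ic, direction in zip(internals, directions):
            L = ic.length
            helical = rng.random((B, L)) < p_h
            n_helical += helical.sum(axis=1)
            phi = np.tile(np.concatenate([[0.0], ic.phi]), (B, 1))
            psi = np.tile(np.concatenate([ic.psi, [0.0]]), (B, 1))
            coil = ~helical
            n_coil = int(coil.sum())
            if n_coil:
                phi_s = rng.uniform(*COIL_PHI_RANGE, size=n_coil)
                psi_s = rng.uniform(*COIL_PSI_RANGE, size=n_coil)
                phi[coil] = phi_s
                psi[coil] = psi_s
                last = coil[:, -1]
                if last.any():
                    phi[last, -1] = rng.uniform(
                        *COIL_PHI_RANGE_TERMINAL, size=int(last.sum())
                    )
            bb = _rebuild_chains(ic, phi, psi)
            H = _place_h_batch(bb, ic.resnames)
            sides = _place_sidechains_batch(bb, ic)

            # jitter non-dihedral atoms of coil residues
            for arr in (bb["O"], H, sides[SIDECHAIN_COM_ATOM], sides[CHARGED_GROUP_ATOM]):
                jit = rng.uniform(-COIL_JITTER, COIL_JITTER, size=arr.shape)
                arr += np.where(coil[:, :, None], jit, 0.0)

            shift = np.where(associated, 0.0, model.separation_distance)[:, None]
            offset = shift * direction[None, :]
            for nm, arr in (("N", bb["N"]), ("CA", bb["CA"]), ("C", bb["C"]),
                            ("O", bb["O"]), ("H", H),
                            (SIDECHAIN_COM_ATOM, sides[SIDECHAIN_COM_ATOM]),
                            (CHARGED_GROUP_ATOM, sides[CHARGED_GROUP_ATOM])):
                idx = ic.idx[nm]
                valid = idx >= 0
                coords[:, idx[valid]] = arr[:, valid] + offset[:, None, :]

        from .interactions import count_sidechain_contacts_batch

        n_contacts = count_sidechain_contacts_batch(coords, sc_all, sc_chain)
        energy = (
            -model.energy_scale_helix * n_helical
            - model.energy_scale_contact * n_contacts
            + rng.normal(0.0, model.noise_sd, size=B)
        )
        ensembles[float(t)] = Ensemble(folded, coords)
        for f in range(B):
            rows.append(
                (
                    float(t),
                    f,
                    float(energy[f]),
                    int(n_helical[f]),
                    100.0 * n_helical[f] / n_res_total,
                    int(n_contacts[f]),
                    bool(associated[f]),
                )
            )

    table = pd.DataFrame(
        rows,
        columns=[
            "temperature_K",
            "frame",
            "energy_kJmol",
            "n_helical",
            "helix_content_pct",
            "hydrophobic_contacts",
            "associated",
        ],
    )
    return ReplicaSeries(ladder, table, ensembles)


# ---------------------------------------------------------------------------
# Toy thermodynamic systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Harmonic1D:
    """1-D harmonic well U(x) = k x^2 / 2, k in kJ/mol/A^2."""

    k: float

    def __post_init__(self):
        if not self.k > 0:
            raise ValueError("force constant k must be positive")


@dataclass(frozen=True)
class TwoState:
    """Two-level system with energies 0 and ``delta_e`` kJ/mol."""

    delta_e: float

    def __post_init__(self):
        if not np.isfinite(self.delta_e):
            raise ValueError("delta_e must be finite")


def generate_toy_thermo_samples(system, temperatures, n: int, seed: int) -> ReplicaSeries:
    """Exact Boltzmann samples of a toy system at each temperature.

    Harmonic sampling is Gaussian with variance kB*T/k and exact
    energies; two-state occupancies follow the Boltzmann ratio
    exp(-delta_e / kB T). The coordinate column is ``x`` (the position,
    or the state indicator for the two-level system).
    """
    temperatures = np.asarray(temperatures, float)
    if np.any(np.diff(temperatures) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for t in temperatures:
        if isinstance(system, Harmonic1D):
            x = rng.normal(0.0, np.sqrt(KB * t / system.k), size=n)
            e = 0.5 * system.k * x * x
        elif isinstance(system, TwoState):
            w = np.exp(-system.delta_e / (KB * t))
            p_excited = w / (1.0 + w)
            x = (rng.random(n) < p_excited).astype(float)
            e = x * system.delta_e
        else:
            raise ValueError(f"unknown toy system: {system!r}")
        for f in range(n):
            rows.append((float(t), f, float(e[f]), float(x[f])))
    table = pd.DataFrame(rows, columns=["temperature_K", "frame", "energy_kJmol", "x"])
    return ReplicaSeries(temperatures, table, None)
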