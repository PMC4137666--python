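"""Batched vector geometry: angles, dihedrals and internal-coordinate
(NeRF) atom placement.

All functions broadcast over leading axes; coordinates sit on the last
axis of length 3. Angles are in degrees.
"""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize vectors along ``axis``; zero vectors raise."""
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle a-b-c at vertex b."""
    u = unit(np.asarray(a, float) - b)
    w = unit(np.asarray(c, float) - b)
    cos = np.clip(np.sum(u * w, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def dihedral_deg(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle of the four points, IUPAC convention, in
    (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = unit(b1)
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def nerf_place(a, b, c, bond, angle, torsion) -> np.ndarray:
    """Place atom D given the positions of A, B, C and the internal
    coordinates |CD| = ``bond``, angle(B,C,D) = ``angle`` and dihedral
    (A,B,C,D) = ``torsion``.

    The standard natural-extension reference frame construction; the
    returned point reproduces the requested internal coordinates exactly
    (round-trip with :func:`dihedral_deg` / :func:`angle_deg`).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bond = np.asarray(bond, float)[..., None]
    ang = np.radians(np.asarray(angle, float))[..., None]
    tor = np.radians(np.asarray(torsion, float))[..., None]

    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    comps = np.broadcast_arrays(
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    )
    d_local = np.concatenate(comps, axis=-1)
    return (
        c
        + d_local[..., :1] * bc
        + d_local[..., 1:2] * m
        + d_local[..., 2:3] * n
    )


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal least-squares rigid superposition of ``mobile`` onto
    ``reference`` (both (n, 3), matched order).

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1); the transform maps ``mobile @ rotation.T + translation``
    onto the reference frame.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("superposition needs two equal (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def principal_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and dominant principal direction of an (n, 3) point cloud."""
    X = np.asarray(points, float)
    centroid = X.mean(axis=0)
    _, _, vt = np.linalg.svd(X - centroid, full_matrices=False)
    axis = vt[0]
    # orient along +z-ish for reproducibility
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return centroid, axis
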