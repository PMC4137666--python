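"""Superposition-based descriptors and decoy clustering.

RMSD series use the first frame as reference; RMSF is computed about the
iteratively superposed mean structure and averaged over the equivalent
residues of the monomers; the supercoil radius is measured from smoothed
local helical-axis points; decoys are clustered by the
largest-neighbor-count algorithm with a pairwise CA-RMSD cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure import Ensemble, Structure
from .vecmath import kabsch, principal_axis

logger = logging.getLogger(__name__)


def superpose(
    mobile: Structure,
    reference: Structure,
    selection: str | tuple = "CA",
):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``
    over the atoms named in ``selection`` (matched order).

    Returns ``(rotation, translation, rmsd)``; the rotation is proper
    (determinant +1) and ``mobile.coords @ rotation.T + translation``
    lies on the reference.
    """
    msel = mobile.coords[mobile.atom_mask(selection)]
    rsel = reference.coords[reference.atom_mask(selection)]
    if msel.shape != rsel.shape:
        raise ValueError(
            f"selected atom counts differ: {msel.shape[0]} vs {rsel.shape[0]}"
        )
    return kabsch(msel, rsel)


def rmsd_series(ensemble: Ensemble, selection: str | tuple = "CA") -> np.ndarray:
    """Frame-wise CA RMSD to the first frame, after superposition."""
    if ensemble.n_frames < 1:
        raise ValueError("empty ensemble")
    mask = ensemble.topology.atom_mask(selection)
    ref = ensemble.coords[0][mask]
    out = np.empty(ensemble.n_frames)
    out[0] = 0.0
    for i in range(1, ensemble.n_frames):
        _, _, out[i] = kabsch(ensemble.coords[i][mask], ref)
    return out


def _superposed_stack(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        R, t, _ = kabsch(coords[i], ref)
        out[i] = coords[i] @ R.T + t
    return out


def rmsf_per_residue(ensemble: Ensemble, monomer_average: bool = True):
    """Per-residue CA root-mean-square fluctuation about the mean
    structure.

    Frames are superposed (whole assembly) onto the running mean in two
    passes; with ``monomer_average`` the fluctuations of equivalent
    residues across chains are averaged, giving one value per monomer
    residue. Returns ``(resids, rmsf)``.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    mask = ensemble.topology.atom_mask("CA")
    X = ensemble.coords[:, mask]
    ref = X[0]
    for _ in range(2):
        X_fit = _superposed_stack(X, ref)
        ref = X_fit.mean(axis=0)
    X = _superposed_stack(X, ref)
    mean = X.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))

    chain_ids = ensemble.topology.chain_ids[mask]
    resids = ensemble.topology.resids[mask]
    if not monomer_average:
        return resids.copy(), rmsf
    uniq = np.unique(resids)
    out = np.array([rmsf[resids == r].mean() for r in uniq])
    del chain_ids
    return uniq, out


def estimate_supercoil_radius(structure: Structure, window: int = 5) -> float:
    """Supercoil radius R0: mean distance of smoothed local helical-axis
    points (window-``window`` CA centroids per chain) from the global
    supercoil axis (principal axis of all CA atoms)."""
    chains = structure.chains
    if len(chains) < 2:
        raise ValueError("supercoil radius needs at least 2 chains")
    ca_all = structure.coords[structure.atom_mask("CA")]
    centroid, axis = principal_axis(ca_all)
    dists = []
    for cid in chains:
        ch = structure.chain(cid)
        ca = ch.coords[ch.atom_mask("CA")]
        if len(ca) < window + 3:
            raise ValueError(f"chain {cid} too short for radius estimation")
        smooth = np.stack(
            [ca[i: i + window].mean(axis=0) for i in range(len(ca) - window + 1)]
        )
        rel = smooth - centroid
        perp = rel - np.outer(rel @ axis, axis)
        dists.append(np.linalg.norm(perp, axis=1))
    return float(np.mean(np.concatenate(dists)))


@dataclass
class ClusterResult:
    """Decoy clustering outcome.

    ``clusters`` is the ordered list of (center model index, member
    indices including the center); members are disjoint and cover the
    selected model set. ``final_model`` is the center of the most
    populated cluster.
    """

    clusters: list[tuple[int, list[int]]]
    selected: list[int]
    top_n: int
    rms_cutoff: float

    @property
    def final_model(self) -> int:
        best = max(
            self.clusters,
            key=lambda c: (len(c[1]), -self._energy_rank[c[0]]),
        )
        return best[0]

    _energy_rank: dict = None  # filled by cluster_by_neighbors


def pairwise_ca_rmsd(ensemble: Ensemble, indices=None) -> np.ndarray:
    """Symmetric matrix of pairwise CA RMSD after superposition."""
    mask = ensemble.topology.atom_mask("CA")
    idx = list(range(ensemble.n_frames)) if indices is None else list(indices)
    X = ensemble.coords[np.asarray(idx)][:, mask]
    n = len(idx)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch(X[j], X[i])
            out[i, j] = out[j, i] = r
    return out


def cluster_by_neighbors(
    models: Ensemble,
    energies,
    top_n: int = 400,
    rms_cutoff: float = 3.0,
) -> ClusterResult:
    """Greedy largest-neighbor-count clustering of the lowest-energy
    decoys.

    The ``top_n`` lowest-energy models are selected; iteratively, the
    unassigned model with the most unassigned neighbors (pairwise CA
    RMSD <= cutoff, excluding itself) becomes a cluster center and takes
    its neighbors with it, until every selected model is assigned. Ties
    on neighbor count break toward the lower-energy model.
    """
    energies = np.asarray(energies, float)
    if len(energies) != models.n_frames:
        raise ValueError("one energy per model required")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if top_n > models.n_frames:
        logger.warning(
            "top_n=%d exceeds model count %d; using all models",
            top_n,
            models.n_frames,
        )
        top_n = models.n_frames

    order = np.argsort(energies, kind="stable")
    selected = [int(i) for i in order[:top_n]]
    D = pairwise_ca_rmsd(models, selected)
    neigh = (D <= rms_cutoff) & ~np.eye(len(selected), dtype=bool)

    # rank by energy for deterministic tie-breaks (lower energy = lower rank)
    energy_rank = {m: r for r, m in enumerate(selected)}

    unassigned = np.ones(len(selected), dtype=bool)
    clusters: list[tuple[int, list[int]]] = []
    while unassigned.any():
        counts = (neigh & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        best_count = counts.max()
        candidates = np.flatnonzero(counts == best_count)
        center_local = min(candidates, key=lambda i: energy_rank[selected[i]])
        members_local = np.flatnonzero(
            (neigh[center_local] & unassigned)
        ).tolist()
        members_local = [center_local] + members_local
        unassigned[members_local] = False
        clusters.append(
            (selected[center_local], sorted(selected[i] for i in members_local))
        )

    result = ClusterResult(clusters, selected, top_n, rms_cutoff)
    result._energy_rank = energy_rank
    return result
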