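"""Multiple-histogram reweighting (WHAM) over a temperature ladder.

Samples collected at many temperatures are combined into an estimate of
the density of states on an (energy, coord1, coord2) grid via the
self-consistent multiple-histogram equations, then projected to the
probability surface P(coord1, coord2) at a target temperature T0. The
free energy is -kB*T0*ln P with its minimum shifted to zero; empty bins
are masked (NaN), not stored as infinities.

The iteration runs in log space, so arbitrarily large beta*E values are
safe. Because every bin of one energy slice shares the same reweighting
denominator, the self-consistent loop only touches per-energy-bin
counts and is cheap even for fine coordinate grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import KB
from .structure import ReplicaSeries

logger = logging.getLogger(__name__)


@dataclass
class ConvergenceReport:
    iterations: int
    final_residual: float
    converged: bool
    residual_history: np.ndarray


@dataclass
class FreeEnergySurface:
    """2-D probability / free-energy grid at the target temperature."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray  # (nx, ny), sums to 1 over occupied bins
    free_energy: np.ndarray  # kJ/mol, min 0, NaN where empty
    t0: float
    coords: tuple
    convergence: ConvergenceReport

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def marginal_mean(self, axis: int = 0) -> float:
        centers = self.x_centers if axis == 0 else self.y_centers
        marg = self.probability.sum(axis=1 - axis)
        return float(np.sum(centers * marg))


def _edges(values: np.ndarray, n: int, vrange=None) -> np.ndarray:
    if vrange is None:
        lo, hi = float(np.min(values)), float(np.max(values))
        if hi <= lo:
            hi = lo + 1.0
        pad = 1e-9 * (hi - lo)
        lo, hi = lo - pad, hi + pad
    else:
        lo, hi = map(float, vrange)
    return np.linspace(lo, hi, n + 1)


def _digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.digitize(values, edges) - 1
    return np.clip(idx, 0, len(edges) - 2)


def wham_reweight(
    series: ReplicaSeries,
    coords,
    t0: float,
    e_bins: int = 200,
    xy_bins=(50, 50),
    tol: float = 1e-7,
    max_iter: int = 10000,
    window_fraction: float = 0.5,
    xy_range=None,
) -> FreeEnergySurface:
    """Ferrenberg-Swendsen multiple-histogram estimate of the 2-D
    probability surface at temperature ``t0``.

    ``coords`` names one or two per-frame observable columns of the
    series table (one coordinate yields a degenerate second axis).
    ``xy_range`` optionally fixes (min, max) per coordinate, e.g.
    ((0, 100), (0, 100)) for percentage coordinates. Only the final
    ``window_fraction`` of frames per replica is used.
    """
    if isinstance(coords, str):
        coords = (coords,)
    coords = tuple(coords)
    if len(coords) == 1:
        coords = (coords[0], coords[0])
        if xy_range is not None and len(xy_range) == 1:
            xy_range = (xy_range[0], xy_range[0])
    data = series.window(window_fraction)
    if "energy_kJmol" not in data.columns or data["energy_kJmol"].isna().any():
        raise ValueError(
            "WHAM needs a per-frame 'energy_kJmol' column; the observable "
            "tables supplied have no energies"
        )
    for c in coords:
        if c not in data.columns:
            raise KeyError(f"reaction coordinate column not found: {c!r}")

    temps = series.temperatures
    betas = 1.0 / (KB * temps)
    beta0 = 1.0 / (KB * t0)
    state_of = {float(t): k for k, t in enumerate(temps)}
    state = data["temperature_K"].map(lambda t: state_of[float(t)]).to_numpy()
    energies = data["energy_kJmol"].to_numpy(float)
    n_k = np.bincount(state, minlength=len(temps)).astype(float)
    if np.any(n_k == 0):
        raise ValueError("every ladder temperature needs samples")

    e_edges = _edges(energies, e_bins)
    e_idx = _digitize(energies, e_edges)
    e_centers = 0.5 * (e_edges[:-1] + e_edges[1:])

    nx, ny = xy_bins
    xr = xy_range or (None, None)
    x_edges = _edges(data[coords[0]].to_numpy(float), nx, xr[0])
    y_edges = _edges(data[coords[1]].to_numpy(float), ny, xr[1])
    x_idx = _digitize(data[coords[0]].to_numpy(float), x_edges)
    y_idx = _digitize(data[coords[1]].to_numpy(float), y_edges)

    # histograms: per energy bin, and per (energy, x, y) bin
    m_e = np.bincount(e_idx, minlength=e_bins).astype(float)
    occ = m_e > 0
    m_exy = np.zeros((e_bins, nx, ny))
    np.add.at(m_exy, (e_idx, x_idx, y_idx), 1.0)

    e_occ = e_centers[occ]
    log_m = np.log(m_e[occ])
    neg_be = -np.outer(betas, e_occ)  # (K, E_occ)
    log_nk = np.log(n_k)

    f = np.zeros(len(temps))
    residuals = []
    converged = False
    for it in range(1, max_iter + 1):
        log_d = logsumexp(log_nk[:, None] + f[:, None] + neg_be, axis=0)
        f_new = -logsumexp(log_m[None, :] - log_d[None, :] + neg_be, axis=1)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        residuals.append(resid)
        f = f_new
        if resid < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "WHAM did not converge after %d iterations (residual %.3g); "
            "returning the partial result",
            max_iter,
            residuals[-1],
        )
    report = ConvergenceReport(
        len(residuals), residuals[-1], converged, np.asarray(residuals)
    )

    # project to the (x, y) surface at t0
    log_d = logsumexp(log_nk[:, None] + f[:, None] + neg_be, axis=0)
    log_w = -beta0 * e_occ - log_d
    log_w -= log_w.max()
    w = np.exp(log_w)
    P = np.tensordot(w, m_exy[occ], axes=(0, 0))
    total = P.sum()
    if total <= 0:
        raise ValueError("empty histograms: no samples fell inside the grid")
    P /= total

    with np.errstate(divide="ignore"):
        F = np.where(P > 0, -KB * t0 * np.log(np.where(P > 0, P, 1.0)), np.nan)
    F = F - np.nanmin(F)
    return FreeEnergySurface(
        x_edges, y_edges, P, F, float(t0), coords, report
    )


# ---------------------------------------------------------------------------
# Basin detection
# ---------------------------------------------------------------------------

@dataclass
class Basin:
    x: float
    y: float
    ix: int
    iy: int
    mass: float
    peak_probability: float


def find_basins(surface: FreeEnergySurface, min_separation: int = 3) -> list[Basin]:
    """Local probability maxima of the surface, ordered by attached
    probability mass.

    A maximum must strictly exceed its 3x3 neighborhood (a flat surface
    therefore has none); maxima closer than ``min_separation`` bins are
    merged into the higher one. Mass is assigned by steepest-ascent
    watershed on the grid.
    """
    P = surface.probability
    nx, ny = P.shape
    pad = np.full((nx + 2, ny + 2), -np.inf)
    pad[1:-1, 1:-1] = P

    # steepest-ascent parent of every bin (index into flattened grid)
    neigh_shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    stacked = np.stack(
        [pad[1 + di: 1 + di + nx, 1 + dj: 1 + dj + ny] for di, dj in neigh_shifts]
    )
    best = np.argmax(stacked, axis=0)  # ties -> first shift, deterministic
    strict_max = np.all(
        stacked[[k for k, s in enumerate(neigh_shifts) if s != (0, 0)]]
        < P[None, :, :],
        axis=0,
    ) & (P > 0)

    maxima = [(int(i), int(j)) for i, j in zip(*np.nonzero(strict_max))]
    if not maxima:
        return []
    maxima.sort(key=lambda ij: (-P[ij], ij))
    kept: list[tuple[int, int]] = []
    merged_to: dict[tuple[int, int], tuple[int, int]] = {}
    for ij in maxima:
        host = None
        for k in kept:
            if np.hypot(ij[0] - k[0], ij[1] - k[1]) < min_separation:
                host = k
                break
        if host is None:
            kept.append(ij)
            merged_to[ij] = ij
        else:
            merged_to[ij] = host

    # follow ascent paths to a strict maximum (path compression)
    di = np.array([s[0] for s in neigh_shifts])
    dj = np.array([s[1] for s in neigh_shifts])
    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pi = np.clip(I + di[best], 0, nx - 1)
    pj = np.clip(J + dj[best], 0, ny - 1)
    for _ in range(nx + ny):
        pi, pj = pi[pi, pj], pj[pi, pj]

    mass = {k: 0.0 for k in kept}
    for i in range(nx):
        for j in range(ny):
            if P[i, j] <= 0:
                continue
            root = (int(pi[i, j]), int(pj[i, j]))
            host = merged_to.get(root)
            if host is not None:
                mass[host] += P[i, j]

    xc, yc = surface.x_centers, surface.y_centers
    basins = [
        Basin(float(xc[i]), float(yc[j]), i, j, mass[(i, j)], float(P[i, j]))
        for i, j in kept
    ]
    basins.sort(key=lambda b: -b.mass)
    return basins
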