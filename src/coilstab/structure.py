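"""In-memory containers: a ``Structure`` (atoms grouped into residues and
chains), a multi-frame ``Ensemble`` sharing one topology, and the
``ReplicaSeries`` holding per-temperature ensembles with per-frame
pseudo-energies and observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Structure:
    """A set of atoms with chain, residue and name labels.

    Atoms belonging to one residue are stored contiguously; residues of a
    chain appear in sequence order. Coordinates are in Angstrom.
    """

    atom_names: np.ndarray  # (n,) str
    chain_ids: np.ndarray  # (n,) str
    resids: np.ndarray  # (n,) int, 1-based within chain
    resnames: np.ndarray  # (n,) 3-letter str
    coords: np.ndarray  # (n, 3) float

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if not (
            len(self.chain_ids) == len(self.resids) == len(self.resnames) == n
            and self.coords.shape == (n, 3)
        ):
            raise ValueError("inconsistent atom array lengths")

    # -- basic queries ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    def atom_mask(self, names) -> np.ndarray:
        names = {names} if isinstance(names, str) else set(names)
        return np.fromiter(
            (a in names for a in self.atom_names), bool, self.n_atoms
        )

    def select(self, mask: np.ndarray) -> "Structure":
        return Structure(
            self.atom_names[mask],
            self.chain_ids[mask],
            self.resids[mask],
            self.resnames[mask],
            self.coords[mask],
        )

    def chain(self, chain_id: str) -> "Structure":
        return self.select(self.chain_ids == chain_id)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, float)
        if coords.shape != self.coords.shape:
            raise ValueError("coordinate shape mismatch")
        return Structure(
            self.atom_names, self.chain_ids, self.resids, self.resnames, coords
        )

    # -- residue bookkeeping ----------------------------------------------

    def residue_table(self) -> pd.DataFrame:
        """One row per residue: chain, resid, resname and the contiguous
        atom slice [start, stop)."""
        rows = []
        start = 0
        for i in range(1, self.n_atoms + 1):
            if (
                i == self.n_atoms
                or self.chain_ids[i] != self.chain_ids[start]
                or self.resids[i] != self.resids[start]
            ):
                rows.append(
                    (
                        self.chain_ids[start],
                        int(self.resids[start]),
                        self.resnames[start],
                        start,
                        i,
                    )
                )
                start = i
        return pd.DataFrame(
            rows, columns=["chain", "resid", "resname", "start", "stop"]
        )

    def residue_atom(self, chain: str, resid: int, name: str) -> np.ndarray:
        """Coordinates of a uniquely named atom of one residue."""
        mask = (
            (self.chain_ids == chain)
            & (self.resids == resid)
            & (self.atom_names == name)
        )
        idx = np.flatnonzero(mask)
        if len(idx) != 1:
            raise KeyError(f"atom {chain}/{resid}/{name}: {len(idx)} matches")
        return self.coords[idx[0]]


@dataclass
class Ensemble:
    """Frames sharing one topology: ``coords`` has shape (n_frames, n_atoms, 3)."""

    topology: Structure
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (
            self.topology.n_atoms,
            3,
        ):
            raise ValueError("ensemble coordinates must be (frames, atoms, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass
class ReplicaSeries:
    """Per-temperature ensembles with per-frame scalars.

    ``table`` has one row per (temperature, frame) with at least the
    columns ``temperature_K`` and ``frame``; ``energy_kJmol`` and
    observable columns are added by the generators and the analysis
    stage. ``ensembles`` maps a temperature to its :class:`Ensemble`
    (absent for scalar toy systems).
    """

    temperatures: np.ndarray
    table: pd.DataFrame
    ensembles: dict[float, Ensemble] | None = field(default=None)

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperature ladder must be strictly increasing")

    def frames_at(self, temperature: float) -> pd.DataFrame:
        sel = self.table[np.isclose(self.table["temperature_K"], temperature)]
        return sel.sort_values("frame")

    def window(self, window_fraction: float = 0.5) -> pd.DataFrame:
        """Final ``window_fraction`` of frames at every temperature (the
        analysis window), concatenated."""
        if not 0 < window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")
        parts = []
        for t in self.temperatures:
            rows = self.frames_at(t)
            n = len(rows)
            keep = max(1, int(np.ceil(n * window_fraction)))
            parts.append(rows.iloc[n - keep:])
        return pd.concat(parts, ignore_index=True)
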