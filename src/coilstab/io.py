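"""File formats: multi-model PDB ensembles (via Biopython), delimited
observable tables, ladder files and FASTA sequences.
"""

from __future__ import annotations

import glob
import logging
import os
import warnings

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from .structure import Ensemble, ReplicaSeries, Structure

logger = logging.getLogger(__name__)

_ELEMENT_GUESS = {"SC": "C", "SQ": "C"}


def _element(atom_name: str) -> str:
    if atom_name in _ELEMENT_GUESS:
        return _ELEMENT_GUESS[atom_name]
    stripped = "".join(c for c in atom_name if c.isalpha())
    return stripped[0].upper() if stripped else "C"


def write_pdb(obj: Structure | Ensemble, path: str) -> None:
    """Write a structure or an ensemble as a (multi-model) PDB file with
    MODEL/ENDMDL records; coordinates keep PDB's 3-decimal precision."""
    frames = [obj] if isinstance(obj, Structure) else list(obj)
    builder = StructureBuilder()
    builder.init_structure("coil")
    for m, frame in enumerate(frames):
        builder.init_model(m + 1)  # PDB models are 1-based
        seen_chain = None
        serial = 1
        res = frame.residue_table()
        for row in res.itertuples():
            if row.chain != seen_chain:
                builder.init_chain(row.chain)
                builder.init_seg("    ")
                seen_chain = row.chain
            builder.init_residue(row.resname, " ", int(row.resid), " ")
            for j in range(row.start, row.stop):
                name = str(frame.atom_names[j])
                builder.init_atom(
                    name,
                    frame.coords[j].astype(float),
                    0.0,
                    1.0,
                    " ",
                    f" {name:<3s}"[:4] if len(name) < 4 else name,
                    serial,
                    _element(name),
                )
                serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(path)


def read_structure_ensemble(path: str) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    All models must share one topology (same chains, residues and atom
    names in the same order); a mismatch raises an error naming the
    offending model.
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            bio = parser.get_structure("coil", path)
        except Exception as exc:
            raise ValueError(f"malformed PDB file {path!r}: {exc}") from exc

    frames = []
    topo_key = None
    for model in bio:
        names, chains, resids, resnames, coords = [], [], [], [], []
        for chain in model:
            for residue in chain:
                het, resid, _ = residue.id
                if het.strip():
                    continue
                for atom in residue:
                    names.append(atom.get_name())
                    chains.append(chain.id)
                    resids.append(int(resid))
                    resnames.append(residue.get_resname())
                    coords.append(atom.coord)
        key = list(zip(names, chains, resids, resnames))
        if topo_key is None:
            topo_key = key
        elif key != topo_key:
            raise ValueError(
                f"model {model.id + 1} of {path!r} does not match the "
                "topology of model 1"
            )
        frames.append(
            Structure(names, chains, resids, resnames, np.array(coords, float))
        )
    if not frames:
        raise ValueError(f"no models found in {path!r}")
    return Ensemble(frames[0], np.stack([f.coords for f in frames]))


# ---------------------------------------------------------------------------
# Observable tables
# ---------------------------------------------------------------------------

def write_observable_table(table: pd.DataFrame, path: str) -> None:
    """Tab-delimited per-frame observable table with header."""
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_observable_tables(path: str) -> ReplicaSeries:
    """Read one delimited observable table, or every ``*.tsv`` of a
    directory, into a :class:`ReplicaSeries` (no coordinates).

    Requires ``temperature_K`` and ``frame`` columns; duplicate
    (temperature, frame) rows and non-numeric cells are errors. A
    missing ``energy_kJmol`` column is allowed — downstream reweighting
    will refuse it with an explicit message.
    """
    if os.path.isdir(path):
        files = sorted(glob.glob(os.path.join(path, "*.tsv")))
        if not files:
            raise FileNotFoundError(f"no *.tsv observable tables in {path!r}")
    else:
        files = [path]
    parts = []
    for f in files:
        df = pd.read_csv(f, sep="\t")
        for col in ("temperature_K", "frame"):
            if col not in df.columns:
                raise ValueError(f"{f!r}: missing required column {col!r}")
        parts.append(df)
    data = pd.concat(parts, ignore_index=True)
    for col in data.columns:
        vals = pd.to_numeric(data[col], errors="coerce")
        if vals.isna().any() and not data[col].isna().any():
            bad = data[col][vals.isna()].iloc[0]
            raise ValueError(f"non-numeric cell {bad!r} in column {col!r}")
        data[col] = vals
    dup = data.duplicated(subset=["temperature_K", "frame"])
    if dup.any():
        row = data[dup].iloc[0]
        raise ValueError(
            "duplicate (temperature, frame) row: "
            f"({row['temperature_K']}, {int(row['frame'])})"
        )
    data = data.sort_values(["temperature_K", "frame"]).reset_index(drop=True)
    temps = np.sort(data["temperature_K"].unique())
    return ReplicaSeries(temps, data, None)


def read_ladder(path: str) -> np.ndarray:
    """Ladder file: one temperature (K) per line; '#' comments allowed."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                values.append(float(line))
    return np.asarray(values)


def write_ladder(ladder, path: str) -> None:
    with open(path, "w") as fh:
        for t in np.asarray(ladder, float):
            fh.write(f"{t:.2f}\n")


def read_fasta_sequence(path: str) -> str:
    """First record of a FASTA file as an upper-case one-letter string."""
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path!r}")
    return str(records[0].seq).upper()
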