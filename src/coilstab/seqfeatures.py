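"""Sequence-level analyses: heptad-register assignment, lipobox motif
scanning, hydropathy profiling and pH-dependent protonation assignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    AA1_TO_AA3,
    AA3_TO_AA1,
    DEFAULT_PKA,
    HYDROPHOBIC_SET,
    KYTE_DOOLITTLE,
    STANDARD_AA,
)
from .structure import Structure

HEPTAD_LETTERS = "abcdefg"
LIPOBOX_RE = re.compile(r"(?=(L[AS][GA]C))")

#: Mature-chain numbering: mature residue 1 corresponds to full-length
#: residue 22 (the lipidated cysteine), i.e. full-length minus this offset.
MATURE_NUMBERING_OFFSET = 21


@dataclass(frozen=True)
class HeptadAssignment:
    """Heptad register of a sequence.

    ``offset`` places residue ``i`` (0-based) at heptad position
    ``"abcdefg"[(i + offset) % 7]``; ``score`` is the fraction of a/d
    slots occupied by residues of the hydrophobic set.
    """

    offset: int
    positions: str
    n_complete_heptads: int
    score: float


def heptad_positions(length: int, offset: int) -> str:
    return "".join(HEPTAD_LETTERS[(i + offset) % 7] for i in range(length))


def _ad_score(sequence: str, offset: int, hydrophobic_set) -> float:
    slots = [
        i for i in range(len(sequence))
        if HEPTAD_LETTERS[(i + offset) % 7] in ("a", "d")
    ]
    if not slots:
        return 0.0
    return sum(sequence[i] in hydrophobic_set for i in slots) / len(slots)


def assign_heptad_register(
    sequence: str, hydrophobic_set=HYDROPHOBIC_SET
) -> HeptadAssignment:
    """Choose the register offset that maximizes hydrophobic occupancy of
    the core-facing a/d positions; ties break toward the smallest offset.
    """
    sequence = str(sequence).upper()
    if len(sequence) < 7:
        raise ValueError("sequence shorter than one heptad")
    hydrophobic_set = {c.upper() for c in hydrophobic_set}
    scores = [_ad_score(sequence, o, hydrophobic_set) for o in range(7)]
    offset = int(np.argmax(scores))  # argmax returns the first (smallest) tie
    return HeptadAssignment(
        offset=offset,
        positions=heptad_positions(len(sequence), offset),
        n_complete_heptads=len(sequence) // 7,
        score=scores[offset],
    )


def scan_lipobox(sequence: str) -> list[tuple[int, tuple[int, int]]]:
    """All lipobox matches L-(A/S)-(G/A)-C.

    Returns ``(cys_position, (cys_position - 1, cys_position))`` per
    match, 1-based: the signal peptidase cleaves immediately before the
    lipidated cysteine.
    """
    sequence = str(sequence).upper()
    out = []
    for m in LIPOBOX_RE.finditer(sequence):
        cys = m.start() + 4  # 1-based position of the C
        out.append((cys, (cys - 1, cys)))
    return out


def hydrophobicity_profile(sequence: str, window: int = 7) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy per position;
    windows are truncated at the sequence ends."""
    sequence = str(sequence).upper()
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(sequence):
        raise ValueError("window longer than sequence")
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue letter(s): {sorted(bad)}")
    vals = np.array([KYTE_DOOLITTLE[c] for c in sequence])
    half = window // 2
    out = np.empty(len(sequence))
    for i in range(len(sequence)):
        lo = max(0, i - half)
        hi = min(len(sequence), i + half + 1)
        out[i] = vals[lo:hi].mean()
    return out


# ---------------------------------------------------------------------------
# Protonation
# ---------------------------------------------------------------------------

_TITRATABLE = {"ASP", "GLU", "HIS", "LYS", "ARG"}
_CARBOXYL = {"ASP", "GLU"}


@dataclass
class ProtonationState:
    """Deterministic protonation assignment at a given pH.

    A titratable group is protonated iff pH < pKa (strict), which makes
    the assignment monotone: lowering the pH never deprotonates a group.
    ``table`` holds one row per titratable side chain; terminal flags are
    stored per chain.
    """

    ph: float
    pka_table: dict
    table: pd.DataFrame
    cterm: dict[str, bool] = field(default_factory=dict)
    nterm: dict[str, bool] = field(default_factory=dict)

    def is_sidechain_protonated(self, chain: str, resid: int) -> bool:
        sel = self.table[
            (self.table["chain"] == chain) & (self.table["resid"] == resid)
        ]
        return bool(sel["protonated"].any())

    def cterm_protonated(self, chain: str) -> bool:
        return self.cterm.get(chain, False)

    def nterm_protonated(self, chain: str) -> bool:
        return self.nterm.get(chain, False)

    @property
    def protonated_carboxyls(self) -> list[tuple[str, int]]:
        """(chain, resid) of every protonated Asp/Glu side chain."""
        sel = self.table[
            self.table["resname"].isin(_CARBOXYL) & self.table["protonated"]
        ]
        return [(r.chain, int(r.resid)) for r in sel.itertuples()]


def _residue_records(residues):
    """Normalize input to (chain, resid, resname3) records."""
    if isinstance(residues, Structure):
        res = residues.residue_table()
        return [(r.chain, int(r.resid), r.resname) for r in res.itertuples()]
    if isinstance(residues, str):
        recs = []
        for i, c in enumerate(residues.upper()):
            if c not in AA1_TO_AA3:
                raise ValueError(f"unknown residue code: {c!r}")
            recs.append(("A", i + 1, AA1_TO_AA3[c]))
        return recs
    recs = []
    for chain, resid, resname in residues:
        resname = str(resname).upper()
        if len(resname) == 1:
            if resname not in AA1_TO_AA3:
                raise ValueError(f"unknown residue code: {resname!r}")
            resname = AA1_TO_AA3[resname]
        elif resname not in AA3_TO_AA1:
            raise ValueError(f"unknown residue code: {resname!r}")
        recs.append((chain, int(resid), resname))
    return recs


def assign_protonation(residues, ph: float, pka_table=None) -> ProtonationState:
    """Threshold-pKa protonation of every titratable group.

    ``residues`` may be a one-letter sequence string (treated as one
    chain), a :class:`Structure`, or an iterable of (chain, resid,
    resname) records. Both chain termini are titrated per chain.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError("pH must be within [0, 14]")
    pka = dict(DEFAULT_PKA)
    if pka_table:
        pka.update(pka_table)
    recs = _residue_records(residues)

    rows = []
    for chain, resid, resname in recs:
        if resname in _TITRATABLE:
            rows.append(
                (chain, resid, resname, pka[resname], ph < pka[resname])
            )
    table = pd.DataFrame(
        rows, columns=["chain", "resid", "resname", "pka", "protonated"]
    )
    chains = {c for c, _, _ in recs}
    cterm = {c: ph < pka["CTERM"] for c in chains}
    nterm = {c: ph < pka["NTERM"] for c in chains}
    return ProtonationState(ph, pka, table, cterm, nterm)
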