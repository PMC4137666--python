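"""Synthetic benchmark sequences.

``LIC80_SYNTHETIC`` is a constructed, SYNTHETIC stand-in for the mature
80-residue chain of an acid-stable trimeric lipoprotein: it is not a
real protein sequence. It carries the documented feature set — an
alanine-rich a/d heptad core, aspartates at mature positions 6/15/37/50
and glutamates at 23/64/65/68/71, a cysteine at mature position 1, and
four methionines plus one phenylalanine in core positions near the
C-terminus. ``SIGNAL_PEPTIDE_SYNTHETIC`` prepends a hydrophobic signal
peptide ending in the L-S-G of a lipobox, so the full-length precursor
has its lipobox at residues 19-22 and cleavage site 21|22.
"""

from __future__ import annotations


def _build_mature() -> str:
    # heptad template abcdefg = A K Q A S K Q  (A at the core a/d slots)
    seq = list((("AKQASKQ") * 12)[:80])
    seq[0] = "C"  # lipidated cysteine, mature position 1
    seq[1] = "A"  # position 2 controls membrane sorting
    for pos in (6, 15, 37, 50):
        seq[pos - 1] = "D"
    for pos in (23, 64, 65, 68, 71):
        seq[pos - 1] = "E"
    for pos in (57, 60, 67, 74):  # methionines in a/d core slots
        seq[pos - 1] = "M"
    seq[78 - 1] = "F"  # phenylalanine near the C-terminal end (a slot)
    return "".join(seq)


#: Synthetic mature 80-residue chain (see module docstring).
LIC80_SYNTHETIC = _build_mature()

#: Synthetic 21-residue signal peptide ending in L-S-G.
SIGNAL_PEPTIDE_SYNTHETIC = "MKKLLAVLVAALAGAVAALSG"

#: Synthetic full-length precursor: signal peptide + mature chain.
LIC_PRECURSOR_SYNTHETIC = SIGNAL_PEPTIDE_SYNTHETIC + LIC80_SYNTHETIC

assert len(SIGNAL_PEPTIDE_SYNTHETIC) == 21
assert len(LIC80_SYNTHETIC) == 80
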