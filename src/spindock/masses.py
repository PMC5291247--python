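"""Monoisotopic masses for peptide and cross-linker arithmetic.

Atomic masses are CODATA/AME2020 values. Residue masses are the standard
monoisotopic residue (i.e. dehydrated) masses of the 20 canonical amino acids.
"""

from __future__ import annotations

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "H1_MASS",
    "H2_MASS",
    "RESIDUE_MASSES",
    "peptide_mass",
    "BS2G_BRIDGE_LIGHT",
    "BS2G_BRIDGE_HEAVY",
    "BS2G_ISOTOPE_DELTA",
    "BS2G_SPACER_LENGTH",
]

H1_MASS = 1.00782503207  # 1H
H2_MASS = 2.01410177785  # 2H
C12_MASS = 12.0
N14_MASS = 14.0030740048
O16_MASS = 15.9949146196
S32_MASS = 31.97207100

PROTON_MASS = 1.007276466812
WATER_MASS = 2 * H1_MASS + O16_MASS  # 18.0105646863

RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146372057,
    "A": 71.03711378471,
    "S": 87.03202840427,
    "P": 97.05276384885,
    "V": 99.06841391299,
    "T": 101.04767846841,
    "C": 103.00918478471,
    "L": 113.08406397713,
    "I": 113.08406397713,
    "N": 114.04292744114,
    "D": 115.02694302383,
    "Q": 128.05857750528,
    "K": 128.09496301399,
    "E": 129.04259308797,
    "M": 131.04048491299,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102359,
    "Y": 163.06332853255,
    "W": 186.07931294985,
}


def peptide_mass(sequence: str) -> float:
    """Monoisotopic neutral mass of an unmodified linear peptide."""
    try:
        return sum(RESIDUE_MASSES[aa] for aa in sequence) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r} in {sequence!r}") from exc


# Glutarate bridge left after both NHS esters of the d0 linker have reacted:
# C5H4O2 as the net addition bridging two amines.
BS2G_BRIDGE_LIGHT = 5 * C12_MASS + 4 * H1_MASS + 2 * O16_MASS  # 96.02113 Da
BS2G_ISOTOPE_DELTA = 4 * (H2_MASS - H1_MASS)  # 4.02511 Da
BS2G_BRIDGE_HEAVY = BS2G_BRIDGE_LIGHT + BS2G_ISOTOPE_DELTA
BS2G_SPACER_LENGTH = 7.7  # Angstrom
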