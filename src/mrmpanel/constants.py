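"""Physical constants for peptide mass spectrometry.

Monoisotopic residue masses (Da) for the 20 canonical amino acids, taken
from the standard published atomic-composition tables used across
proteomics software. Stored as data so they can be swapped without code
changes (e.g. for average masses or custom residue chemistries).
"""

from __future__ import annotations

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic residue masses, Da (residue = amino acid minus water).
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
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
    "K": 128.09496301400,
    "E": 129.04259308797,
    "M": 131.04048491299,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102360,
    "Y": 163.06332853255,
    "W": 186.07931294986,
}

#: Monoisotopic mass of H2O, Da.
WATER_MONO = 18.0105646837

#: Mass of a proton, Da.
PROTON = 1.00727646677

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), Da.
CARBAMIDOMETHYL = 57.02146372057
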