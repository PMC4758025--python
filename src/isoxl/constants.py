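"""Single source of truth for physical constants used across the package.

All masses are monoisotopic (the data model targets Orbitrap-class
instruments; average masses are never used). Values are CODATA/IUPAC
standard atomic masses, frozen here so results are bit-stable.
"""

from __future__ import annotations

from types import MappingProxyType

# -- atomic monoisotopic masses (Da) ----------------------------------------
MASS_H = 1.00782503207          # 1H
MASS_D = 2.01410177785          # 2H
MASS_C = 12.0
MASS_N = 14.0030740048
MASS_O = 15.9949146196
MASS_S = 31.97207100

MASS_PROTON = 1.00727646688
MASS_WATER = 2 * MASS_H + MASS_O        # 18.0105646...
MASS_OXIDATION = MASS_O                 # methionine oxidation, +15.9949 Da

#: heavy-minus-light shift for a d12-coded linker: 12 x (m(2H) - m(1H))
HEAVY_LIGHT_SHIFT = 12 * (MASS_D - MASS_H)   # 12.07532...

# -- amino-acid residue monoisotopic masses (Da) ----------------------------
RESIDUE_MASSES = MappingProxyType({
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
    "M": 131.04048508847,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102359,
    "Y": 163.06332853255,
    "W": 186.07931294985,
})

# -- BS3 linker bridge ------------------------------------------------------
# After reaction of both NHS esters with primary amines, the residual bridge
# is the suberic-acid diacyl group C8H10O2 (two amide bonds formed, the two
# amine hydrogens lost).
BS3_BRIDGE_LIGHT = 8 * MASS_C + 10 * MASS_H + 2 * MASS_O      # 138.06808 Da
BS3_DEADEND_LIGHT = BS3_BRIDGE_LIGHT + MASS_WATER             # 156.07864 Da
BS3_SPACER_LENGTH = 11.4     # Angstrom, maximum N-N reach of the spacer

# -- van der Waals radii for the SAS grid (Angstrom) ------------------------
# Hydrogens are ignored (crystal structures rarely resolve them).
VDW_RADII = MappingProxyType({
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
})
VDW_DEFAULT = 1.70

#: reactive atom per residue class for amine/hydroxyl-directed cross-linkers
REACTIVE_ATOMS = MappingProxyType({
    "LYS": "NZ",
    "SER": "OG",
    "THR": "OG1",
    "TYR": "OH",
})
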