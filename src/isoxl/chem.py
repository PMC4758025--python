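"""Mass bookkeeping: residues, modifications, the isotope-coded BS3 linker,
and peptide/precursor/fragment mass arithmetic.

Conventions
-----------
* All masses are neutral monoisotopic Da unless a function name says m/z.
* Precursor masses are stored as neutral masses internally; converters to
  and from m/z are provided for file I/O.
* A linker "attachment" is one of ``cross-link`` (bridge between two sites),
  ``dead-end`` (one end hydrolyzed, adds bridge + water) or ``loop`` (both
  ends on one peptide, adds the bare bridge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from .constants import (
    BS3_BRIDGE_LIGHT,
    BS3_SPACER_LENGTH,
    HEAVY_LIGHT_SHIFT,
    MASS_OXIDATION,
    MASS_PROTON,
    MASS_WATER,
    RESIDUE_MASSES,
)


class LinkerForm(str, Enum):
    LIGHT = "light"
    HEAVY = "heavy"


class Attachment(str, Enum):
    CROSS_LINK = "cross-link"
    DEAD_END = "dead-end"
    LOOP = "loop"


class ConfigurationError(ValueError):
    """Raised for invalid enum members / linker configuration."""


class InputError(ValueError):
    """Raised for malformed user input (sequences, files, parameters)."""


@dataclass(frozen=True)
class LinkerSpec:
    """An isotope-coded amine-reactive cross-linker.

    ``first_site_residues`` are the residues accepted at the first
    (anchoring) site, ``second_site_residues`` at the second; protein
    N-termini are always accepted at either site. For BS3 the first class
    (K) is a subset of the second (K/S/T/Y).
    """

    name: str = "BS3"
    spacer_length: float = BS3_SPACER_LENGTH
    bridge_light: float = BS3_BRIDGE_LIGHT
    heavy_shift: float = HEAVY_LIGHT_SHIFT
    first_site_residues: frozenset[str] = frozenset({"K"})
    second_site_residues: frozenset[str] = frozenset({"K", "S", "T", "Y"})

    def __post_init__(self) -> None:
        if self.spacer_length <= 0:
            raise ConfigurationError("spacer_length must be positive")
        if not self.first_site_residues <= self.second_site_residues:
            raise ConfigurationError(
                "first site residue class must be a subset of the second")

    def mass_delta(self, form: LinkerForm | str,
                   attachment: Attachment | str) -> float:
        """Neutral mass added to the peptide(s) by the linker."""
        try:
            form = LinkerForm(form)
            attachment = Attachment(attachment)
        except ValueError as exc:
            raise ConfigurationError(str(exc)) from None
        if attachment is Attachment.DEAD_END:
            base = self.bridge_light + MASS_WATER
        else:  # cross-link and loop both add the bare bridge
            base = self.bridge_light
        if form is LinkerForm.HEAVY:
            base += self.heavy_shift
        return base


BS3 = LinkerSpec()


def linker_mass_delta(form: LinkerForm | str, attachment: Attachment | str,
                      linker: LinkerSpec = BS3) -> float:
    return linker.mass_delta(form, attachment)


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide located in its parent protein (1-based, inclusive).

    ``modifications`` is a tuple of ``(position, mass_delta_da, label)``
    with positions in peptide coordinates.
    """

    protein_id: str
    sequence: str
    start: int
    end: int
    missed_cleavages_K: int = 0
    missed_cleavages_R: int = 0
    modifications: tuple[tuple[int, float, str], ...] = ()
    is_protein_nterm: bool = False
    is_protein_cterm: bool = False
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise InputError(
                f"peptide coordinates [{self.start},{self.end}] inconsistent "
                f"with sequence length {len(self.sequence)}")
        for pos, _, _ in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise InputError(f"modification position {pos} outside peptide")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mod_mass(self) -> float:
        return sum(delta for _, delta, _ in self.modifications)

    def neutral_mass(self, linker_contrib: float = 0.0) -> float:
        return peptide_neutral_mass(self, linker_contrib)

    def with_modifications(
            self, mods: tuple[tuple[int, float, str], ...]) -> "Peptide":
        return replace(self, modifications=mods)


def sequence_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of an unmodified peptide sequence."""
    total = MASS_WATER
    for i, aa in enumerate(sequence, start=1):
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise InputError(
                f"unknown residue {aa!r} at position {i}") from None
    return total


def peptide_neutral_mass(p: Peptide, linker_contrib: float = 0.0) -> float:
    """Residue masses + water + modification deltas + any linker mass."""
    return sequence_mass(p.sequence) + p.mod_mass + linker_contrib


def mass_to_mz(neutral_mass: float, z: int) -> float:
    if z < 1:
        raise InputError("charge must be >= 1")
    return (neutral_mass + z * MASS_PROTON) / z


def mz_to_neutral_mass(mz: float, z: int) -> float:
    if z < 1:
        raise InputError("charge must be >= 1")
    return mz * z - z * MASS_PROTON
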