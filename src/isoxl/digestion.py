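"""Protein database handling and in-silico tryptic digestion.

Trypsin cleaves C-terminal to K and R; missed cleavages are budgeted per
residue type (default K:3, R:1) rather than as a single total. Cleavage
before proline is suppressed by default (classic trypsin behaviour),
configurable off.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import InputError, Peptide, peptide_neutral_mass
from .constants import MASS_OXIDATION

DECOY_PREFIX = "REV_"


@dataclass
class ProteinDB:
    """A FASTA-backed protein database; entries are (id, description, seq)."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)
    is_decoy: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pid, _, seq in self.entries:
            if pid in seen:
                raise InputError(f"duplicate protein id {pid!r}")
            seen.add(pid)
            if not seq:
                raise InputError(f"empty sequence for {pid!r}")
            if not seq.isupper() or not seq.isalpha():
                raise InputError(f"sequence for {pid!r} must be uppercase letters")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def sequence(self, protein_id: str) -> str:
        for pid, _, seq in self.entries:
            if pid == protein_id:
                return seq
        raise KeyError(protein_id)


def read_fasta(path: str | Path, is_decoy: bool = False) -> ProteinDB:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entries.append((rec.id, rec.description, str(rec.seq).upper()))
    if not entries:
        raise InputError(f"no FASTA records in {path}")
    return ProteinDB(entries, is_decoy=is_decoy)


def write_fasta(db: ProteinDB, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description=desc if desc != pid else "")
        for pid, desc, seq in db.entries
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def reverse_decoy(db: ProteinDB) -> ProteinDB:
    """Reversed-sequence decoy database; ids get a ``REV_`` prefix.

    Reversal is an involution, so a decoy of a decoy restores the original
    sequence (the prefix is stripped again).
    """
    entries = []
    for pid, desc, seq in db.entries:
        rev = seq[::-1]
        if rev == seq:
            warnings.warn(
                f"decoy of {pid!r} is identical to the target (palindrome)")
        if pid.startswith(DECOY_PREFIX):
            new_id = pid[len(DECOY_PREFIX):]
        else:
            new_id = DECOY_PREFIX + pid
        entries.append((new_id, desc, rev))
    return ProteinDB(entries, is_decoy=not db.is_decoy)


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based indices i such that trypsin cleaves between i and i+1."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR":
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(sequence: str, protein_id: str = "", *, max_missed_K: int = 3,
           max_missed_R: int = 1, proline_rule: bool = True,
           is_decoy: bool = False) -> list[Peptide]:
    """Fully tryptic peptides with per-residue-type missed-cleavage limits.

    Returns every substring bounded by cleavage sites (or protein ends)
    whose internal K-site count <= max_missed_K and internal R-site count
    <= max_missed_R, with protein coordinates and terminal flags. No mass
    window is applied here; see :func:`digest_with_modifications`.
    """
    if not sequence:
        raise InputError("empty protein sequence")
    if max_missed_K < 0 or max_missed_R < 0:
        raise InputError("missed-cleavage limits must be >= 0")
    sites = cleavage_sites(sequence, proline_rule)
    # segment boundaries: start indices of fully-cleaved segments
    starts = [0] + [s + 1 for s in sites]
    ends = [s for s in sites] + [len(sequence) - 1]   # inclusive 0-based
    n_seg = len(starts)
    peptides: list[Peptide] = []
    for i in range(n_seg):
        missed_K = missed_R = 0
        for j in range(i, n_seg):
            if j > i:
                boundary = sequence[ends[j - 1]]
                if boundary == "K":
                    missed_K += 1
                else:
                    missed_R += 1
                if missed_K > max_missed_K or missed_R > max_missed_R:
                    break
            peptides.append(Peptide(
                protein_id=protein_id,
                sequence=sequence[starts[i]:ends[j] + 1],
                start=starts[i] + 1,
                end=ends[j] + 1,
                missed_cleavages_K=missed_K,
                missed_cleavages_R=missed_R,
                is_protein_nterm=(starts[i] == 0),
                is_protein_cterm=(ends[j] == len(sequence) - 1),
                is_decoy=is_decoy,
            ))
    return peptides


def enumerate_modified_forms(p: Peptide, max_mox: int = 2) -> list[Peptide]:
    """All variable-modification forms: methionine oxidation, <= max_mox sites."""
    met_positions = [i + 1 for i, aa in enumerate(p.sequence) if aa == "M"]
    forms = [p]
    for k in range(1, max_mox + 1):
        for combo in itertools.combinations(met_positions, k):
            mods = tuple((pos, MASS_OXIDATION, "Oxidation") for pos in combo)
            forms.append(p.with_modifications(p.modifications + mods))
    return forms


def digest_with_modifications(
        db: ProteinDB, *, max_missed_K: int = 3, max_missed_R: int = 1,
        max_mox: int = 2, mass_min: float = 200.0, mass_max: float = 5000.0,
        proline_rule: bool = True) -> list[Peptide]:
    """Digest every protein, enumerate oxidation forms, apply the mass window.

    The 200-5000 Da window is applied to the modified peptide mass (before
    any linker contribution).
    """
    out: list[Peptide] = []
    for pid, _, seq in db.entries:
        decoy = db.is_decoy or pid.startswith(DECOY_PREFIX)
        for pep in digest(seq, pid, max_missed_K=max_missed_K,
                          max_missed_R=max_missed_R, proline_rule=proline_rule,
                          is_decoy=decoy):
            for form in enumerate_modified_forms(pep, max_mox):
                m = peptide_neutral_mass(form)
                if mass_min <= m <= mass_max:
                    out.append(form)
    return out
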