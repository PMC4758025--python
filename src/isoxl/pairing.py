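"""Light/heavy isotope-pair validation of cross-link identifications.

A cross-link assignment is accepted only if three criteria hold:

1. *dual identification* — the same peptide(s), link sites, and
   modifications are identified with both the light (H12) and the heavy
   (D12) form of the linker, with the precursor masses differing by the
   d12 shift (12.0753 Da) within a ppm tolerance;
2. *co-elution* — the two precursors elute simultaneously (|dRT| within
   tolerance), because the isotopologues are chemically near-identical;
3. *pattern similarity* — the two MS2 fragmentation patterns agree
   (Jaccard similarity of matched fragment labels above a threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .constants import HEAVY_LIGHT_SHIFT
from .search import PSM, trypsin_consistency


@dataclass
class IsotopePairResult:
    light: PSM
    heavy: PSM
    delta_mass_error_ppm: float
    delta_rt: float
    pattern_similarity: float = 0.0
    dual_identification: bool = False
    co_elution: bool = False
    pattern_similar: bool = False
    verdict: str = "rejected"
    failed_criteria: tuple[str, ...] = ()


def precursor_shift_error_ppm(light_mass: float, heavy_mass: float,
                              expected_shift: float = HEAVY_LIGHT_SHIFT,
                              ) -> float:
    """Deviation of (heavy - light) from the d12 shift, in ppm of the
    light precursor mass (instrument error is ppm-scaled)."""
    return (heavy_mass - light_mass - expected_shift) / light_mass * 1e6


def pattern_similarity(light: PSM, heavy: PSM, *,
                       shift_tol_da: float = 0.1) -> float:
    """Jaccard similarity of matched fragment-label sets.

    Labels (series, index, source, charge) are linker-form independent, so
    linker-containing fragments are comparable even though their m/z
    differ. For labels matched in both spectra the observed m/z shift must
    be ~0 (linker-free) or ~12.0753/z (linker-containing); inconsistent
    labels are dropped from the intersection.
    """
    mz_light = dict(light.matched)
    mz_heavy = dict(heavy.matched)
    a, b = set(mz_light), set(mz_heavy)
    if not a or not b:
        warnings.warn("pattern similarity of an unannotated PSM is 0")
        return 0.0
    union = a | b
    inter = set()
    for lbl in a & b:
        z = lbl[3]
        shift = mz_heavy[lbl] - mz_light[lbl]
        if (abs(shift) <= shift_tol_da
                or abs(shift - HEAVY_LIGHT_SHIFT / z) <= shift_tol_da):
            inter.add(lbl)
    return len(inter) / len(union)


def find_pairs(light_psms: list[PSM], heavy_psms: list[PSM], *,
               mass_tol_ppm: float = 5.0, rt_tol_min: float = 0.5,
               expected_shift: float = HEAVY_LIGHT_SHIFT,
               ) -> tuple[list[IsotopePairResult], list[tuple[PSM, str]]]:
    """Pair light and heavy PSMs under criteria 1 (dual id + mass shift)
    and 2 (co-elution).

    Pairing is 1:1 greedy by descending score sum (ties by smaller |dRT|,
    then deterministic key order). Returns (pairs, unpaired) where each
    unpaired PSM carries the reason no partner was found.
    """
    by_key_heavy: dict[tuple, list[int]] = {}
    for j, h in enumerate(heavy_psms):
        by_key_heavy.setdefault(h.candidate.assignment_key, []).append(j)

    edges = []
    reasons: dict[int, str] = {}
    for i, l in enumerate(light_psms):
        key = l.candidate.assignment_key
        if key not in by_key_heavy:
            reasons[i] = "no heavy identification"
            continue
        any_mass = any_rt = False
        for j in by_key_heavy[key]:
            h = heavy_psms[j]
            err = precursor_shift_error_ppm(l.precursor_mass,
                                            h.precursor_mass, expected_shift)
            drt = h.retention_time - l.retention_time
            mass_ok = abs(err) <= mass_tol_ppm
            rt_ok = abs(drt) <= rt_tol_min
            any_mass |= mass_ok
            any_rt |= rt_ok
            if mass_ok and rt_ok:
                edges.append((-(l.score + h.score), abs(drt), i, j, err, drt))
        if i not in reasons and not any(e[2] == i for e in edges):
            reasons[i] = ("mass shift outside tolerance" if not any_mass
                          else "retention times do not co-elute")

    pairs: list[IsotopePairResult] = []
    used_light: set[int] = set()
    used_heavy: set[int] = set()
    for _, _, i, j, err, drt in sorted(edges):
        if i in used_light or j in used_heavy:
            continue
        used_light.add(i)
        used_heavy.add(j)
        pairs.append(IsotopePairResult(
            light=light_psms[i], heavy=heavy_psms[j],
            delta_mass_error_ppm=err, delta_rt=drt,
            dual_identification=True, co_elution=True))

    unpaired: list[tuple[PSM, str]] = []
    for i, l in enumerate(light_psms):
        if i not in used_light:
            unpaired.append((l, reasons.get(i, "partner taken by a better pair")))
    matched_keys = {p.heavy.candidate.assignment_key for p in pairs}
    light_keys = {l.candidate.assignment_key for l in light_psms}
    for j, h in enumerate(heavy_psms):
        if j not in used_heavy:
            if h.candidate.assignment_key not in light_keys:
                unpaired.append((h, "no light identification"))
            elif h.candidate.assignment_key not in matched_keys:
                unpaired.append((h, "mass shift or co-elution failed"))
            else:
                unpaired.append((h, "partner taken by a better pair"))
    return pairs, unpaired


def validate_pair(pair: IsotopePairResult, *,
                  similarity_min: float = 0.6) -> IsotopePairResult:
    """Evaluate criterion 3 and set the verdict (all three must hold)."""
    pair.pattern_similarity = pattern_similarity(pair.light, pair.heavy)
    pair.pattern_similar = pair.pattern_similarity >= similarity_min
    failed = []
    if not pair.dual_identification:
        failed.append("dual_identification")
    if not pair.co_elution:
        failed.append("co_elution")
    if not pair.pattern_similar:
        failed.append("pattern_similar")
    pair.failed_criteria = tuple(failed)
    pair.verdict = "validated" if not failed else "rejected"
    return pair


def validate_pairs(light_psms: list[PSM], heavy_psms: list[PSM], *,
                   mass_tol_ppm: float = 5.0, rt_tol_min: float = 0.5,
                   similarity_min: float = 0.6,
                   ) -> tuple[list[IsotopePairResult], list[tuple[PSM, str]]]:
    pairs, unpaired = find_pairs(light_psms, heavy_psms,
                                 mass_tol_ppm=mass_tol_ppm,
                                 rt_tol_min=rt_tol_min)
    pairs = [validate_pair(p, similarity_min=similarity_min) for p in pairs]
    return pairs, unpaired


def link_id(pair: IsotopePairResult) -> tuple:
    """Collapse a peptide-level pair to a unique residue-pair link:
    the sorted ((protein, residue position)) pair.

    Redundant peptide identifications (missed cleavages, oxidation forms)
    of the same cross-linked residue pair map to one link.
    """
    c = pair.light.candidate
    a = c.site_residue("alpha")[:2]
    if c.beta is not None or c.xl_type == "intra-peptide-loop":
        b = c.site_residue("beta")[:2]
    else:
        b = a
    return tuple(sorted((a, b))) + (c.xl_type,)


def pairs_to_table(pairs: list[IsotopePairResult]) -> pd.DataFrame:
    """Validated cross-link table (machine-readable result summary)."""
    rows = []
    for p in pairs:
        c = p.light.candidate
        sa = c.site_residue("alpha")
        sb = (c.site_residue("beta")
              if c.beta is not None or c.xl_type == "intra-peptide-loop"
              else sa)
        rows.append({
            "protein1": sa[0], "site1": sa[1], "site1_kind": sa[2],
            "protein2": sb[0], "site2": sb[1], "site2_kind": sb[2],
            "peptide1": c.alpha.sequence,
            "peptide2": c.beta.sequence if c.beta is not None else "",
            "xl_type": c.xl_type,
            "light_scan": p.light.scan_id, "heavy_scan": p.heavy.scan_id,
            "light_score": round(p.light.score, 4),
            "heavy_score": round(p.heavy.score, 4),
            "delta_mass_ppm": round(p.delta_mass_error_ppm, 4),
            "delta_rt_min": round(p.delta_rt, 4),
            "similarity": round(p.pattern_similarity, 4),
            "trypsin": trypsin_consistency(c),
            "decoy": p.light.is_decoy or p.heavy.is_decoy,
            "verdict": p.verdict,
            "failed_criteria": ";".join(p.failed_criteria),
        })
    return pd.DataFrame(rows)
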