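"""Cross-linked peptide search: candidate enumeration against observed
precursors, theoretical b/y fragment generation, spectrum matching, a
binomial-survival PSM score, and decoy-based FDR estimation.

The score is defined here rather than ported from any search engine:
``-10*log10 P(X >= k)`` for ``X ~ Binomial(n, p)`` with ``k`` matched
fragments out of ``n`` theoretical ones and ``p`` the per-fragment
random-match probability, plus an explained-intensity bonus. Score scales
are engine-specific, so confidence thresholds are always derived from the
decoy FDR of the dataset at hand, never hard-coded.
"""

from __future__ import annotations

import bisect
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chem import (
    Attachment,
    BS3,
    InputError,
    LinkerForm,
    LinkerSpec,
    Peptide,
    mass_to_mz,
    peptide_neutral_mass,
    sequence_mass,
)
from .constants import MASS_PROTON, MASS_WATER, RESIDUE_MASSES
from .spectra import Spectrum

NTERM_SITE = 0      # link-site sentinel for an alpha-amine (N-terminal) attachment

XL_INTER = "inter-protein"
XL_INTRA = "intra-protein"
XL_LOOP = "intra-peptide-loop"
XL_DEADEND = "dead-end"


def _pep_key(p: Peptide) -> tuple:
    return (p.protein_id, p.start, p.end, p.sequence, p.modifications)


def first_class_sites(p: Peptide, linker: LinkerSpec = BS3) -> list[int]:
    """Anchoring sites: K side chains and the protein N-terminus.

    A K at peptide position 1 of an N-terminal peptide yields two distinct
    sites (alpha-amine and side chain).
    """
    sites = [i + 1 for i, aa in enumerate(p.sequence)
             if aa in linker.first_site_residues]
    if p.is_protein_nterm:
        sites.insert(0, NTERM_SITE)
    return sites


def second_class_sites(p: Peptide, linker: LinkerSpec = BS3) -> list[int]:
    sites = [i + 1 for i, aa in enumerate(p.sequence)
             if aa in linker.second_site_residues]
    if p.is_protein_nterm:
        sites.insert(0, NTERM_SITE)
    return sites


@dataclass(frozen=True)
class CrossLinkCandidate:
    """A (pair of) peptide(s) joined by one light or heavy linker.

    For dead-end forms ``beta`` is ``None`` and ``link_site_beta`` unused;
    for loop links ``beta`` is ``None`` and both sites lie on ``alpha``.
    Site 0 denotes the protein N-terminus (alpha-amine).
    """

    alpha: Peptide
    beta: Peptide | None
    link_site_alpha: int
    link_site_beta: int | None
    form: LinkerForm
    xl_type: str
    linker: LinkerSpec = BS3

    @property
    def attachment(self) -> Attachment:
        if self.xl_type == XL_DEADEND:
            return Attachment.DEAD_END
        if self.xl_type == XL_LOOP:
            return Attachment.LOOP
        return Attachment.CROSS_LINK

    @property
    def precursor_mass(self) -> float:
        m = peptide_neutral_mass(self.alpha)
        if self.beta is not None:
            m += peptide_neutral_mass(self.beta)
        return m + self.linker.mass_delta(self.form, self.attachment)

    @property
    def is_decoy(self) -> bool:
        return self.alpha.is_decoy or (self.beta is not None and self.beta.is_decoy)

    def site_residue(self, which: str) -> tuple[str, int, str]:
        """Residue-level site id: (protein, 1-based position, kind)."""
        if which == "alpha" or self.beta is None:
            pep, site = self.alpha, (self.link_site_alpha if which == "alpha"
                                     else self.link_site_beta)
        else:
            pep, site = self.beta, self.link_site_beta
        if site == NTERM_SITE:
            return (pep.protein_id, 1, "nterm")
        return (pep.protein_id, pep.start + site - 1, "sidechain")

    @property
    def key(self) -> tuple:
        return (_pep_key(self.alpha),
                _pep_key(self.beta) if self.beta is not None else None,
                self.link_site_alpha, self.link_site_beta,
                self.form.value, self.xl_type)

    @property
    def assignment_key(self) -> tuple:
        """Identity of the assignment ignoring the linker form (light/heavy)."""
        return (_pep_key(self.alpha),
                _pep_key(self.beta) if self.beta is not None else None,
                self.link_site_alpha, self.link_site_beta, self.xl_type)


def make_pair_candidate(pep_a: Peptide, site_a: int, pep_b: Peptide,
                        site_b: int, form: LinkerForm,
                        linker: LinkerSpec = BS3) -> CrossLinkCandidate:
    """Canonicalize an unordered peptide pair: alpha is the longer peptide,
    ties broken lexicographically by sequence (then by site)."""
    order_a = (-len(pep_a.sequence), pep_a.sequence, pep_a.protein_id,
               pep_a.start, site_a)
    order_b = (-len(pep_b.sequence), pep_b.sequence, pep_b.protein_id,
               pep_b.start, site_b)
    if order_b < order_a:
        pep_a, site_a, pep_b, site_b = pep_b, site_b, pep_a, site_a
    xl_type = (XL_INTRA if pep_a.protein_id == pep_b.protein_id else XL_INTER)
    return CrossLinkCandidate(pep_a, pep_b, site_a, site_b, form, xl_type,
                              linker)


class PeptideIndex:
    """Peptides sorted by neutral mass for O(log n) window queries."""

    def __init__(self, peptides: list[Peptide]):
        decorated = sorted(
            ((peptide_neutral_mass(p), _pep_key(p), p) for p in peptides),
            key=lambda t: (t[0], t[1]))
        self.peptides = [p for _, _, p in decorated]
        self.masses = [m for m, _, _ in decorated]

    def in_window(self, lo: float, hi: float) -> list[tuple[float, Peptide]]:
        i = bisect.bisect_left(self.masses, lo)
        j = bisect.bisect_right(self.masses, hi)
        return [(self.masses[k], self.peptides[k]) for k in range(i, j)]


def enumerate_candidates(
        index: PeptideIndex, precursor_mass: float, *, tol_ppm: float = 3.0,
        linker: LinkerSpec = BS3,
        forms: tuple[LinkerForm, ...] = (LinkerForm.LIGHT, LinkerForm.HEAVY),
        include_deadend: bool = True, include_loop: bool = True,
) -> list[CrossLinkCandidate]:
    """All candidates whose computed neutral mass is within ``tol_ppm`` of
    the observed precursor mass, in both linker forms."""
    tol = precursor_mass * tol_ppm * 1e-6
    out: list[CrossLinkCandidate] = []
    seen: set[tuple] = set()

    def emit(c: CrossLinkCandidate) -> None:
        if c.key not in seen:
            seen.add(c.key)
            out.append(c)

    for form in forms:
        # single-peptide forms
        if include_deadend:
            delta = linker.mass_delta(form, Attachment.DEAD_END)
            for _, p in index.in_window(precursor_mass - delta - tol,
                                        precursor_mass - delta + tol):
                for site in first_class_sites(p, linker):
                    emit(CrossLinkCandidate(p, None, site, None, form,
                                            XL_DEADEND, linker))
        if include_loop:
            delta = linker.mass_delta(form, Attachment.LOOP)
            for _, p in index.in_window(precursor_mass - delta - tol,
                                        precursor_mass - delta + tol):
                firsts = first_class_sites(p, linker)
                seconds = second_class_sites(p, linker)
                for s1 in firsts:
                    for s2 in seconds:
                        if s1 != s2:
                            lo, hi = sorted((s1, s2))
                            emit(CrossLinkCandidate(
                                p, None, lo, hi, form, XL_LOOP, linker))
        # two-peptide cross-links
        bridge = linker.mass_delta(form, Attachment.CROSS_LINK)
        rest = precursor_mass - bridge
        for i, (m_a, pep_a) in enumerate(
                zip(index.masses, index.peptides)):
            if m_a > rest / 2 + tol:
                break
            lo, hi = rest - m_a - tol, rest - m_a + tol
            j0 = bisect.bisect_left(index.masses, lo, lo=i)
            j1 = bisect.bisect_right(index.masses, hi, lo=i)
            for j in range(j0, j1):
                pep_b = index.peptides[j]
                a_first = first_class_sites(pep_a, linker)
                a_second = second_class_sites(pep_a, linker)
                b_first = first_class_sites(pep_b, linker)
                b_second = second_class_sites(pep_b, linker)
                pairs = {(sa, sb) for sa in a_first for sb in b_second}
                pairs |= {(sa, sb) for sb in b_first for sa in a_second}
                for sa, sb in sorted(pairs):
                    emit(make_pair_candidate(pep_a, sa, pep_b, sb, form,
                                             linker))
    out.sort(key=lambda c: c.key)
    return out


@dataclass(frozen=True)
class FragmentIon:
    series: str                 # 'b' or 'y'
    index: int
    source: str                 # 'alpha' or 'beta'
    contains_linker: bool
    charge: int
    theoretical_mz: float

    @property
    def label(self) -> tuple:
        """Identity label, independent of linker form (light/heavy)."""
        return (self.series, self.index, self.source, self.charge)


def _prefix_masses(p: Peptide) -> list[float]:
    """Cumulative residue+mod masses; entry i = mass of residues 1..i."""
    mods = {pos: delta for pos, delta, _ in p.modifications}
    acc, out = 0.0, [0.0]
    for i, aa in enumerate(p.sequence, start=1):
        acc += RESIDUE_MASSES[aa] + mods.get(i, 0.0)
        out.append(acc)
    return out


def generate_fragments(c: CrossLinkCandidate, max_charge: int = 2,
                       mz_range: tuple[float, float] = (100.0, 2000.0),
                       ) -> list[FragmentIon]:
    """b/y series for alpha (and beta) at charges 1..max_charge.

    A fragment spanning the link site carries the linker contribution:
    bridge + full partner-peptide mass for two-peptide links, the
    hydrolyzed-linker delta for dead-ends, and the bare bridge for loop
    links (added once if either loop site is covered).
    """
    linker = c.linker
    frags: list[FragmentIon] = []
    peptides = [("alpha", c.alpha)]
    if c.beta is not None:
        peptides.append(("beta", c.beta))

    for source, pep in peptides:
        prefix = _prefix_masses(pep)
        total = prefix[-1]
        length = len(pep)
        if c.xl_type == XL_DEADEND:
            contrib = linker.mass_delta(c.form, Attachment.DEAD_END)
            sites = [c.link_site_alpha]
        elif c.xl_type == XL_LOOP:
            contrib = linker.mass_delta(c.form, Attachment.LOOP)
            sites = [c.link_site_alpha, c.link_site_beta]
        else:
            bridge = linker.mass_delta(c.form, Attachment.CROSS_LINK)
            if source == "alpha":
                partner = peptide_neutral_mass(c.beta)
                sites = [c.link_site_alpha]
            else:
                partner = peptide_neutral_mass(c.alpha)
                sites = [c.link_site_beta]
            contrib = bridge + partner

        def covers_b(i: int) -> bool:
            # b_i spans residues 1..i; an N-term attachment (site 0) is
            # always inside any b ion
            return any(s <= i for s in sites)

        def covers_y(i: int) -> bool:
            # y_i spans residues length-i+1..length
            return any(s >= length - i + 1 and s != NTERM_SITE for s in sites)

        for i in range(1, length):
            b_neutral = prefix[i]
            y_neutral = total - prefix[length - i] + MASS_WATER
            for series, neutral, covered in (
                    ("b", b_neutral, covers_b(i)),
                    ("y", y_neutral, covers_y(i))):
                if covered:
                    neutral = neutral + contrib
                for z in range(1, max_charge + 1):
                    mz = mass_to_mz(neutral, z)
                    if mz_range[0] <= mz <= mz_range[1]:
                        frags.append(FragmentIon(series, i, source, covered,
                                                 z, mz))
    return frags


@dataclass
class MatchedPeak:
    fragment: FragmentIon
    peak_index: int
    observed_mz: float
    intensity: float
    ambiguous: bool = False


@dataclass
class MatchResult:
    matches: list[MatchedPeak]
    surviving_mz: np.ndarray
    surviving_intensity: np.ndarray
    n_theoretical: int


def match_spectrum(s: Spectrum, frags: list[FragmentIon], *,
                   tol_da: float = 0.8, snr_min: float = 2.0) -> MatchResult:
    """Match theoretical fragments to de-noised peaks.

    The noise level is estimated as the median intensity of the
    lower-intensity half of the peaks (robust whether or not fragment
    peaks outnumber noise peaks); peaks below noise x snr_min are
    removed. Each fragment then matches its nearest surviving peak within
    ``tol_da``. One peak may satisfy several fragments (flagged
    ambiguous); each fragment matches at most one peak.
    """
    if s.n_peaks == 0 or not frags:
        return MatchResult([], np.empty(0), np.empty(0), len(frags))
    # the floor never exceeds the base peak: the strongest peaks are
    # signal by definition, whatever the intensity distribution looks like
    floor = min(float(np.quantile(s.intensity, 0.25)) * snr_min,
                float(s.intensity.max()))
    keep = s.intensity >= floor
    mz = s.mz[keep]
    inten = s.intensity[keep]
    matches: list[MatchedPeak] = []
    used: dict[int, int] = {}
    if mz.size:
        for frag in frags:
            pos = int(np.searchsorted(mz, frag.theoretical_mz))
            best, best_err = -1, tol_da
            for cand in (pos - 1, pos):
                if 0 <= cand < mz.size:
                    err = abs(mz[cand] - frag.theoretical_mz)
                    if err <= best_err:
                        best, best_err = cand, err
            if best >= 0:
                used[best] = used.get(best, 0) + 1
                matches.append(MatchedPeak(frag, best, float(mz[best]),
                                           float(inten[best])))
        for m in matches:
            m.ambiguous = used[m.peak_index] > 1
    return MatchResult(matches, mz, inten, len(frags))


def score_psm(result: MatchResult, *, tol_da: float = 0.8) -> float:
    """Binomial-survival score with explained-intensity bonus (>= 0)."""
    n = result.n_theoretical
    if n == 0:
        warnings.warn("no theoretical fragments in range; score 0")
        return 0.0
    k = len({m.fragment.label for m in result.matches})
    if k == 0 or result.surviving_mz.size == 0:
        return 0.0
    span = float(result.surviving_mz[-1] - result.surviving_mz[0])
    span = max(span, 2 * tol_da)
    p = 2.0 * tol_da * result.surviving_mz.size / span
    p = min(max(p, 1e-9), 1 - 1e-9)
    sf = float(stats.binom.sf(k - 1, n, p))
    sf = max(sf, 1e-300)
    base = max(0.0, -10.0 * math.log10(sf))
    total_intensity = float(result.surviving_intensity.sum())
    matched_intensity = sum(
        {m.peak_index: m.intensity for m in result.matches}.values())
    bonus = 20.0 * matched_intensity / total_intensity if total_intensity else 0.0
    return base + bonus


@dataclass
class PSM:
    """A peptide(-pair)-spectrum match."""

    candidate: CrossLinkCandidate
    scan_id: str
    matched: tuple[tuple[tuple, float], ...]   # (fragment label, observed m/z)
    score: float
    precursor_error_ppm: float
    precursor_mass: float
    charge: int
    retention_time: float

    @property
    def is_decoy(self) -> bool:
        return self.candidate.is_decoy

    @property
    def matched_labels(self) -> frozenset:
        return frozenset(lbl for lbl, _ in self.matched)


def trypsin_consistency(c: CrossLinkCandidate) -> str:
    """'violation' if a linked K sits at a tryptic C-terminal boundary.

    Trypsin cannot cleave C-terminal to a cross-linker-modified lysine, so
    a link site on a peptide's C-terminal K implies an impossible cleavage
    — unless that K is the protein C-terminus (no cleavage implied).
    N-terminal (site 0) attachments never imply a cleavage.
    """
    checks = [(c.alpha, c.link_site_alpha)]
    if c.beta is not None:
        checks.append((c.beta, c.link_site_beta))
    elif c.xl_type == XL_LOOP:
        checks.append((c.alpha, c.link_site_beta))
    for pep, site in checks:
        if site is None or site == NTERM_SITE:
            continue
        if (site == len(pep) and pep.sequence[site - 1] == "K"
                and not pep.is_protein_cterm):
            return "violation"
    return "consistent"


def fdr_at_threshold(target_psms: list[PSM], decoy_psms: list[PSM],
                     threshold: float) -> float:
    """Decoy-based FDR estimate: decoys above / max(1, targets above)."""
    n_t = sum(1 for p in target_psms if p.score >= threshold)
    n_d = sum(1 for p in decoy_psms if p.score >= threshold)
    return n_d / max(1, n_t)


def threshold_at_fdr(target_psms: list[PSM], decoy_psms: list[PSM],
                     fdr_target: float) -> float:
    """Smallest score threshold whose estimated FDR is <= fdr_target."""
    scores = sorted({p.score for p in target_psms + decoy_psms})
    for t in scores:
        if fdr_at_threshold(target_psms, decoy_psms, t) <= fdr_target:
            return t
    return math.inf


def search_spectra(spectra: list[Spectrum], index: PeptideIndex, *,
                   linker: LinkerSpec = BS3, tol_ppm: float = 3.0,
                   fragment_tol_da: float = 0.8, snr_min: float = 2.0,
                   max_fragment_charge: int = 2, min_precursor_charge: int = 3,
                   mz_range: tuple[float, float] = (100.0, 2000.0),
                   ) -> dict[LinkerForm, list[PSM]]:
    """Score every spectrum against both linker forms; keep the best PSM
    per spectrum and form (deterministic tie-break by candidate key).

    Spectra with precursor charge below ``min_precursor_charge`` are
    excluded, mirroring instrument-side rejection of 1+/2+ precursors.
    """
    results: dict[LinkerForm, list[PSM]] = {LinkerForm.LIGHT: [],
                                            LinkerForm.HEAVY: []}
    for s in spectra:
        if s.charge < min_precursor_charge:
            continue
        candidates = enumerate_candidates(index, s.precursor_neutral_mass,
                                          tol_ppm=tol_ppm, linker=linker)
        best: dict[LinkerForm, PSM] = {}
        for c in candidates:
            frags = generate_fragments(
                c, max_charge=min(max_fragment_charge, s.charge),
                mz_range=mz_range)
            res = match_spectrum(s, frags, tol_da=fragment_tol_da,
                                 snr_min=snr_min)
            score = score_psm(res, tol_da=fragment_tol_da)
            theo = c.precursor_mass
            psm = PSM(
                candidate=c, scan_id=s.scan_id,
                matched=tuple(sorted((m.fragment.label, m.observed_mz)
                                     for m in res.matches)),
                score=score,
                precursor_error_ppm=(s.precursor_neutral_mass - theo)
                / theo * 1e6,
                precursor_mass=s.precursor_neutral_mass,
                charge=s.charge, retention_time=s.retention_time)
            cur = best.get(c.form)
            if (cur is None or psm.score > cur.score
                    or (psm.score == cur.score
                        and c.key < cur.candidate.key)):
                best[c.form] = psm
        for form, psm in best.items():
            if psm.score > 0:
                results[form].append(psm)
    return results
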