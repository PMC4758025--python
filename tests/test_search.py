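"""Cross-link candidate enumeration (vs. an all-pairs oracle), fragment
generation, spectrum matching, scoring, FDR, and the trypsin rule."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from isoxl.chem import BS3, LinkerForm, Peptide, peptide_neutral_mass
from isoxl.constants import HEAVY_LIGHT_SHIFT
from isoxl.digestion import ProteinDB, digest_with_modifications
from isoxl.search import (
    NTERM_SITE,
    CrossLinkCandidate,
    PeptideIndex,
    enumerate_candidates,
    fdr_at_threshold,
    first_class_sites,
    generate_fragments,
    make_pair_candidate,
    match_spectrum,
    score_psm,
    second_class_sites,
    threshold_at_fdr,
    trypsin_consistency,
)
from isoxl.spectra import Spectrum


def oracle_candidates(peptides, precursor_mass, tol_ppm, linker=BS3):
    """Brute force over all peptides, peptide pairs and site pairs."""
    tol = precursor_mass * tol_ppm * 1e-6
    keys = set()
    for form in (LinkerForm.LIGHT, LinkerForm.HEAVY):
        dead = linker.mass_delta(form, "dead-end")
        bridge = linker.mass_delta(form, "cross-link")
        for p in peptides:
            m = peptide_neutral_mass(p)
            if abs(m + dead - precursor_mass) <= tol:
                for s in first_class_sites(p):
                    keys.add(CrossLinkCandidate(p, None, s, None, form,
                                                "dead-end").key)
            if abs(m + bridge - precursor_mass) <= tol:
                for s1 in first_class_sites(p):
                    for s2 in second_class_sites(p):
                        if s1 != s2:
                            lo, hi = sorted((s1, s2))
                            keys.add(CrossLinkCandidate(
                                p, None, lo, hi, form,
                                "intra-peptide-loop").key)
        for pa, pb in itertools.combinations_with_replacement(peptides, 2):
            total = (peptide_neutral_mass(pa) + peptide_neutral_mass(pb)
                     + bridge)
            if abs(total - precursor_mass) > tol:
                continue
            for sa in first_class_sites(pa):
                for sb in second_class_sites(pb):
                    keys.add(make_pair_candidate(pa, sa, pb, sb, form).key)
            for sb in first_class_sites(pb):
                for sa in second_class_sites(pa):
                    keys.add(make_pair_candidate(pa, sa, pb, sb, form).key)
    return keys


@pytest.fixture(scope="module")
def toy_index():
    db = ProteinDB([("P1", "", "MKGLAKRSTV"), ("P2", "", "AGKYSEK"),
                    ("P3", "", "LLSKMGR")])
    peptides = digest_with_modifications(db, mass_min=0.0, mass_max=1e6)
    return peptides, PeptideIndex(peptides)


class TestEnumerateCandidates:
    def test_no_reactive_sites_yields_empty(self):
        # W/F/V-only protein that is not N-terminally usable has no K/S/T/Y
        p = Peptide("P1", "WFVW", 2, 5)           # not protein N-term
        idx = PeptideIndex([p])
        m = peptide_neutral_mass(p) + BS3.mass_delta("light", "dead-end")
        assert enumerate_candidates(idx, m) == []

    def test_known_pair_found_at_exact_mass(self, toy_index):
        peptides, idx = toy_index
        pa = next(p for p in peptides if p.sequence == "MK" and
                  not p.modifications)
        pb = next(p for p in peptides if p.sequence == "AGK" and
                  not p.modifications)
        target = (peptide_neutral_mass(pa) + peptide_neutral_mass(pb)
                  + BS3.mass_delta("light", "cross-link"))
        keys = {c.key for c in enumerate_candidates(idx, target)}
        wanted = make_pair_candidate(pa, 2, pb, 3, LinkerForm.LIGHT).key
        assert wanted in keys

    def test_10ppm_error_missed_at_3ppm_tolerance(self, toy_index):
        peptides, idx = toy_index
        pa = next(p for p in peptides if p.sequence == "MK")
        pb = next(p for p in peptides if p.sequence == "AGK")
        target = (peptide_neutral_mass(pa) + peptide_neutral_mass(pb)
                  + BS3.mass_delta("light", "cross-link"))
        off = target * (1 + 10e-6)
        assert all(c.precursor_mass != pytest.approx(target, abs=1e-9)
                   for c in enumerate_candidates(idx, off, tol_ppm=3.0))

    @pytest.mark.parametrize("query_offset_ppm", [0.0, 1.5, -2.5])
    def test_equals_bruteforce_oracle(self, toy_index, query_offset_ppm):
        peptides, idx = toy_index
        pa = next(p for p in peptides if p.sequence == "GLAK")
        pb = next(p for p in peptides if p.sequence == "YSEK")
        base = (peptide_neutral_mass(pa) + peptide_neutral_mass(pb)
                + BS3.mass_delta("light", "cross-link"))
        query = base * (1 + query_offset_ppm * 1e-6)
        got = {c.key for c in enumerate_candidates(idx, query)}
        assert got == oracle_candidates(peptides, query, 3.0)

    def test_deadend_masses_match_oracle(self, toy_index):
        peptides, idx = toy_index
        p = next(p for p in peptides if p.sequence == "LLSK")
        query = peptide_neutral_mass(p) + BS3.mass_delta("heavy", "dead-end")
        got = {c.key for c in enumerate_candidates(idx, query)}
        assert got == oracle_candidates(peptides, query, 3.0)
        assert any(c.xl_type == "dead-end" for c in
                   enumerate_candidates(idx, query))


@pytest.fixture
def pair_candidates():
    pa = Peptide("P1", "AKGLSER", 10, 16)
    pb = Peptide("P2", "VMKTS", 3, 7)
    light = make_pair_candidate(pa, 2, pb, 3, LinkerForm.LIGHT)
    heavy = make_pair_candidate(pa, 2, pb, 3, LinkerForm.HEAVY)
    return light, heavy


class TestGenerateFragments:
    def test_linker_free_ions_identical_between_forms(self, pair_candidates):
        light, heavy = pair_candidates
        fl = {f.label: f for f in generate_fragments(light)}
        fh = {f.label: f for f in generate_fragments(heavy)}
        shared = set(fl) & set(fh)
        assert shared
        for lbl in shared:
            if not fl[lbl].contains_linker:
                assert fh[lbl].theoretical_mz == pytest.approx(
                    fl[lbl].theoretical_mz, abs=1e-9)

    def test_linker_ions_shift_12_over_z(self, pair_candidates):
        light, heavy = pair_candidates
        fl = {f.label: f for f in generate_fragments(light)}
        fh = {f.label: f for f in generate_fragments(heavy)}
        checked = 0
        for lbl in set(fl) & set(fh):
            if fl[lbl].contains_linker:
                z = lbl[3]
                assert fh[lbl].theoretical_mz - fl[lbl].theoretical_mz == \
                    pytest.approx(HEAVY_LIGHT_SHIFT / z, abs=1e-9)
                checked += 1
        assert checked > 0

    def test_forms_in_bijection_with_shift_0_or_12_over_z(
            self, pair_candidates):
        light, heavy = pair_candidates
        fl = {f.label: f for f in generate_fragments(
            light, mz_range=(0.0, math.inf))}
        fh = {f.label: f for f in generate_fragments(
            heavy, mz_range=(0.0, math.inf))}
        assert set(fl) == set(fh)
        for lbl, f in fl.items():
            shift = fh[lbl].theoretical_mz - f.theoretical_mz
            expected = HEAVY_LIGHT_SHIFT / lbl[3] if f.contains_linker else 0.0
            assert shift == pytest.approx(expected, abs=1e-9)

    def test_deadend_fragments_carry_hydrolyzed_linker(self):
        p = Peptide("P1", "AKGLR", 1, 5)
        cand = CrossLinkCandidate(p, None, 2, None, LinkerForm.LIGHT,
                                  "dead-end")
        plain = CrossLinkCandidate(p, None, 2, None, LinkerForm.LIGHT,
                                   "dead-end")
        frags = generate_fragments(cand, max_charge=1,
                                   mz_range=(0.0, math.inf))
        assert all(f.source == "alpha" for f in frags)
        by = {(f.series, f.index): f for f in frags}
        # b4 spans the site (pos 2), y2 does not
        assert by[("b", 4)].contains_linker
        assert not by[("y", 2)].contains_linker
        mass_b4_plain = sum(
            [71.03711, 128.09496, 57.02146, 113.08406])  # AKGL residues
        assert by[("b", 4)].theoretical_mz == pytest.approx(
            mass_b4_plain + 156.0786 + 1.00728, abs=1e-3)

    def test_nterm_attachment_marks_all_b_ions(self):
        pa = Peptide("P1", "AGLSER", 1, 6, is_protein_nterm=True)
        pb = Peptide("P2", "VMK", 3, 5)
        cand = make_pair_candidate(pa, NTERM_SITE, pb, 3, LinkerForm.LIGHT)
        for f in generate_fragments(cand, mz_range=(0.0, math.inf)):
            if f.source == "alpha" and f.series == "b":
                assert f.contains_linker
            if f.source == "alpha" and f.series == "y":
                assert not f.contains_linker


class TestMatchAndScore:
    def test_empty_spectrum_matches_nothing(self, pair_candidates):
        light, _ = pair_candidates
        s = Spectrum("s1", 1000.0, 3, 5.0, np.array([]), np.array([]))
        res = match_spectrum(s, generate_fragments(light))
        assert res.matches == []
        assert score_psm(res) == 0.0

    def test_exact_peak_matched_and_boundary_excluded(self):
        p = Peptide("P1", "AKGLR", 1, 5)
        cand = CrossLinkCandidate(p, None, 2, None, LinkerForm.LIGHT,
                                  "dead-end")
        frags = generate_fragments(cand, max_charge=1)
        target = frags[0]
        s_hit = Spectrum("s", 1000.0, 3, 5.0,
                         np.array([target.theoretical_mz]), np.array([10.0]))
        s_miss = Spectrum("s", 1000.0, 3, 5.0,
                          np.array([target.theoretical_mz + 0.9]),
                          np.array([10.0]))
        assert len(match_spectrum(s_hit, [target]).matches) == 1
        assert len(match_spectrum(s_miss, [target], tol_da=0.8).matches) == 0

    def test_score_monotone_in_matched_count(self, pair_candidates):
        light, _ = pair_candidates
        frags = generate_fragments(light, max_charge=1)
        mz_all = np.array(sorted(f.theoretical_mz for f in frags))
        inten = np.full(mz_all.size, 100.0)
        full = Spectrum("s", 2000.0, 3, 5.0, mz_all, inten)
        half = Spectrum("s", 2000.0, 3, 5.0, mz_all[::2], inten[::2])
        score_full = score_psm(match_spectrum(full, frags))
        score_half = score_psm(match_spectrum(half, frags))
        assert score_full > score_half > 0

    def test_score_equals_independent_formula(self):
        """Fixed worked example recomputed from the closed form."""
        p = Peptide("P1", "AKGLR", 1, 5)
        cand = CrossLinkCandidate(p, None, 2, None, LinkerForm.LIGHT,
                                  "dead-end")
        frags = generate_fragments(cand, max_charge=1)
        n = len(frags)
        hit = [f.theoretical_mz for f in frags[:3]]
        noise = [300.0, 500.0, 700.0]
        mz = np.array(sorted(hit + noise))
        inten = np.array([100.0] * mz.size)
        s = Spectrum("s", 1000.0, 3, 5.0, mz, inten)
        res = match_spectrum(s, frags, tol_da=0.8)
        got = score_psm(res, tol_da=0.8)
        # independent recomputation
        k = 3
        span = mz.max() - mz.min()
        p_rand = 2 * 0.8 * mz.size / span
        expected = -10 * math.log10(stats.binom.sf(k - 1, n, p_rand))
        matched_intensity = 100.0 * len({m.peak_index for m in res.matches})
        expected += 20.0 * matched_intensity / inten.sum()
        assert got == pytest.approx(expected, rel=1e-12)


class TestTrypsinConsistency:
    def _pep(self, seq, start, end, cterm=False, nterm=False):
        return Peptide("P1", seq, start, end, is_protein_cterm=cterm,
                       is_protein_nterm=nterm)

    def test_cterminal_link_site_is_violation(self):
        pa = self._pep("AGLK", 5, 8)              # K at cleavage boundary
        pb = self._pep("VMKTS", 20, 24)
        cand = make_pair_candidate(pa, 4, pb, 3, LinkerForm.LIGHT)
        assert trypsin_consistency(cand) == "violation"

    def test_internal_missed_cleavage_site_consistent(self):
        pa = self._pep("AKGLR", 5, 9)
        pb = self._pep("VMKTS", 20, 24)
        cand = make_pair_candidate(pa, 2, pb, 3, LinkerForm.LIGHT)
        assert trypsin_consistency(cand) == "consistent"

    def test_protein_termini_exempt(self):
        pa = self._pep("AGLK", 5, 8, cterm=True)   # protein C-terminal K
        pb = self._pep("AGLSER", 1, 6, nterm=True)
        cand = make_pair_candidate(pb, NTERM_SITE, pa, 4, LinkerForm.LIGHT)
        assert trypsin_consistency(cand) == "consistent"


class _FakePSM:
    def __init__(self, score):
        self.score = score


class TestFdr:
    def test_no_decoys_above_threshold(self):
        targets = [_FakePSM(s) for s in (10, 20, 30)]
        decoys = [_FakePSM(1.0)]
        assert fdr_at_threshold(targets, decoys, 5.0) == 0.0

    def test_equal_counts_give_fdr_one(self):
        targets = [_FakePSM(10)]
        decoys = [_FakePSM(10)]
        assert fdr_at_threshold(targets, decoys, 5.0) == 1.0

    def test_threshold_achieves_requested_fdr(self):
        targets = [_FakePSM(s) for s in (5, 15, 25, 35, 45)]
        decoys = [_FakePSM(s) for s in (6, 12)]
        thr = threshold_at_fdr(targets, decoys, 0.05)
        assert fdr_at_threshold(targets, decoys, thr) <= 0.05
        # threshold is the smallest observed score that satisfies the bound
        below = [s.score for s in targets + decoys if s.score < thr]
        assert all(fdr_at_threshold(targets, decoys, s) > 0.05
                   for s in below)


def test_planted_scores_dominate_noise_scores(full_pipeline_run):
    """True planted PSMs outscore the best noise/decoy assignments."""
    truth, result, _ = full_pipeline_run
    planted, noise = [], []
    for form, psms in result.psms.items():
        for p in psms:
            (planted if p.scan_id in truth.emitted_spectra else noise).append(
                p.score)
    assert planted
    assert np.median(planted) > (max(noise) if noise else 0.0)
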