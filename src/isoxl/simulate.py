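"""Synthetic fixture generator: a toy multi-chain complex with
coordinates, planted cross-links, and paired light/heavy MS2 spectra, so
the whole pipeline is testable end to end without external data.

The generator emulates the study conditions of an isotope-coded BS3
experiment: 1:1 light/heavy labeling (every true link yields one light
and one heavy spectrum, co-eluting, with precursors 12.0753 Da apart),
b/y fragment series with the 12 Da/z shift on linker-containing ions,
log-normal peak intensities, uniform noise peaks, charge >= 3 precursors,
and flexible (optionally unresolved) N-termini that act as cross-linking
hotspots. Coordinates are ideal helical C-alpha traces packed on a grid —
sufficient for distance logic, with no physical energy model.

All randomness flows through one ``numpy`` Generator in a fixed order of
draws, so outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import InputError, LinkerForm, Peptide, peptide_neutral_mass
from .constants import HEAVY_LIGHT_SHIFT
from .digestion import ProteinDB, digest, write_fasta
from .search import (
    NTERM_SITE,
    CrossLinkCandidate,
    generate_fragments,
    make_pair_candidate,
)
from .spectra import Spectrum, write_mgf
from .structure import NTERM, Atom, Residue, StructureModel, reactive_atom, sas_distance

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: residue alphabet and sampling weights: lysine-rich (>= 8% K target),
#: some M for oxidation forms, modest R so tryptic peptides stay long
_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_WEIGHTS = np.array([
    0.06, 0.01, 0.05, 0.06, 0.04, 0.07, 0.02, 0.05, 0.11, 0.08,
    0.04, 0.04, 0.03, 0.04, 0.04, 0.07, 0.06, 0.06, 0.01, 0.06,
])
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()


@dataclass
class TrueLink:
    site_a: tuple[str, int | str]      # (chain, residue position or 'nterm')
    site_b: tuple[str, int | str]
    xl_type: str
    sas: float                          # A, or nan when unconstrained


@dataclass
class GroundTruth:
    proteins: ProteinDB
    structure: StructureModel
    true_links: list[TrueLink] = field(default_factory=list)
    #: scan id -> (link index, linker form, retention time)
    emitted_spectra: dict[str, tuple[int, str, float]] = field(
        default_factory=dict)
    spectra: list[Spectrum] = field(default_factory=list)


def _helix_coords(n: int, origin: np.ndarray) -> np.ndarray:
    """Ideal alpha-helical C-alpha trace: 1.5 A rise, 100 deg per residue,
    2.3 A radius."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.stack([origin[0] + 2.3 * np.cos(theta),
                     origin[1] + 2.3 * np.sin(theta),
                     origin[2] + 1.5 * i], axis=1)


def make_toy_complex(seed: int = 0, *, n_chains: int = 4,
                     chain_length: int = 50,
                     unresolved_nterm_frac: float = 0.5,
                     chain_spacing: float = 17.0,
                     ) -> tuple[ProteinDB, StructureModel]:
    """Random K-rich sequences on ideal helical traces packed on a grid.

    Chain axes are spaced so inter-chain C-alpha distances fall on both
    sides of the 35 A cross-link cutoff. A fraction of chains have their
    first few residues unresolved (no atoms), emulating flexible termini
    missing from crystal structures. Deterministic for a fixed seed.
    """
    if not 1 <= n_chains <= 26:
        raise InputError("n_chains must be in 1..26")
    rng = np.random.default_rng(seed)
    entries = []
    chains: dict[str, list[Residue]] = {}
    letters = [chr(ord("A") + i) for i in range(n_chains)]
    for idx, cid in enumerate(letters):
        seq = "".join(rng.choice(list(_ALPHABET), size=chain_length,
                                 p=_WEIGHTS))
        # guarantee the K density the reactive-site logic needs
        min_k = max(1, int(math.ceil(0.08 * chain_length)))
        positions = [i for i, aa in enumerate(seq) if aa not in "KR"]
        seq_list = list(seq)
        while seq_list.count("K") < min_k and positions:
            j = positions.pop(int(rng.integers(len(positions))))
            seq_list[j] = "K"
        seq = "".join(seq_list)
        entries.append((cid, f"synthetic chain {cid}", seq))

        origin = np.array([(idx % 2) * chain_spacing,
                           (idx // 2) * chain_spacing, 0.0])
        coords = _helix_coords(chain_length, origin)
        unresolved_n = 0
        if rng.random() < unresolved_nterm_frac:
            unresolved_n = int(rng.integers(2, 6))
        residues = []
        for i, aa in enumerate(seq, start=1):
            resolved = i > unresolved_n
            # termini are floppier: higher B toward both chain ends
            b = 30.0 + 40.0 * math.exp(-min(i - 1, chain_length - i) / 5.0) \
                + float(rng.normal(0.0, 3.0))
            atoms = {}
            if resolved:
                atoms["CA"] = Atom("CA", "C", coords[i - 1], round(b, 2))
            residues.append(Residue(cid, i, AA3[aa], resolved, atoms))
        chains[cid] = residues
    return ProteinDB(entries), StructureModel(chains)


def write_pdb(model: StructureModel, db: ProteinDB, path: str | Path) -> None:
    """Write the toy model as plain PDB text (SEQRES + C-alpha ATOM
    records), byte-stable for a fixed model."""
    lines = []
    for pid, _, seq in db.entries:
        n = len(seq)
        for block_no, start in enumerate(range(0, n, 13), start=1):
            names = " ".join(AA3[aa] for aa in seq[start:start + 13])
            lines.append(f"SEQRES {block_no:3d} {pid} {n:4d}  {names:<51s}")
    serial = 1
    for pid, _, _ in db.entries:
        for res in model.chains[pid]:
            for atom in res.atoms.values():
                x, y, z = atom.pos
                lines.append(
                    f"ATOM  {serial:5d}  {atom.name:<3s} {res.name:>3s} "
                    f"{pid}{res.seqid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{atom.b_factor:6.2f}          "
                    f"{atom.element:>2s}")
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _reactive_site_pool(db: ProteinDB) -> tuple[list, list]:
    """(terminal sites, lysine sites) available for planting."""
    terminals, lysines = [], []
    for pid, _, seq in db.entries:
        terminals.append((pid, NTERM))
        for i, aa in enumerate(seq, start=1):
            if aa == "K":
                lysines.append((pid, i))
    return terminals, lysines


def plant_crosslinks(db: ProteinDB, model: StructureModel, n_links: int, *,
                     max_sas: float = 35.0, frac_terminal: float = 0.9,
                     grid_spacing: float = 1.0, seed: int = 0) -> GroundTruth:
    """Sample ``n_links`` reactive site pairs as ground-truth cross-links.

    A fraction ``frac_terminal`` involves a protein N-terminus (the
    flexible-hotspot situation). Pairs whose two sites are both resolved
    must satisfy SAS <= max_sas; a pair with an unresolved site is
    geometrically unconstrained and accepted as-is.
    """
    if max_sas <= 0:
        raise InputError("max_sas must be positive")
    rng = np.random.default_rng(seed)
    terminals, lysines = _reactive_site_pool(db)
    n_terminal = int(round(frac_terminal * n_links))

    def check(site_a, site_b) -> float | None:
        """SAS distance if both sites resolved and reachable, nan when
        unconstrained, None when the pair violates the constraint."""
        ra = reactive_atom(model, site_a[0], site_a[1])
        rb = reactive_atom(model, site_b[0], site_b[1])
        if ra is None or rb is None:
            return math.nan
        if float(np.linalg.norm(ra.pos - rb.pos)) > max_sas:
            return None      # SAS >= Euclidean: no grid search needed
        d = sas_distance(model, ra, rb, grid_spacing=grid_spacing,
                         max_path=max_sas + 3 * grid_spacing)
        return d if d <= max_sas else None

    links: list[TrueLink] = []
    used: set[tuple] = set()
    attempts = 0
    while len(links) < n_links and attempts < 200 * n_links:
        attempts += 1
        want_terminal = len(links) < n_terminal
        if want_terminal:
            a = terminals[int(rng.integers(len(terminals)))]
            b = lysines[int(rng.integers(len(lysines)))]
        else:
            a = lysines[int(rng.integers(len(lysines)))]
            b = lysines[int(rng.integers(len(lysines)))]
        if a == b:
            continue
        key = tuple(sorted((a, b), key=lambda s: (s[0], str(s[1]))))
        if key in used:
            continue
        try:
            pa = peptide_for_site(db, *a)[0]
            pb = peptide_for_site(db, *b)[0]
        except InputError:
            continue        # site not reachable by a valid tryptic peptide
        if a[0] == b[0] and (pa.start, pa.end) == (pb.start, pb.end):
            # sites on one tryptic peptide would be a loop link, not the
            # peptide-pair link this planting models — skip those
            continue
        d = check(a, b)
        if d is None:
            continue
        used.add(key)
        xl_type = "inter-protein" if a[0] != b[0] else "intra-protein"
        links.append(TrueLink(a, b, xl_type, d))
    if len(links) < n_links:
        raise InputError(
            f"only {len(links)} site pairs satisfy SAS <= {max_sas} A; "
            f"requested {n_links}")
    return GroundTruth(db, model, links)


def peptide_for_site(db: ProteinDB, protein: str, site: int | str,
                     *, max_missed_K: int = 3, max_missed_R: int = 1,
                     ) -> tuple[Peptide, int]:
    """Shortest tryptic peptide carrying the site consistently with the
    trypsin rule (a linked K may not sit at a cleavage boundary).

    Returns (peptide, link site in peptide coordinates; 0 = N-terminus).
    """
    peptides = digest(db.sequence(protein), protein,
                      max_missed_K=max_missed_K, max_missed_R=max_missed_R)
    best: tuple[Peptide, int] | None = None
    for p in peptides:
        if site == NTERM:
            if not p.is_protein_nterm or len(p) < 3:
                continue
            cand = (p, NTERM_SITE)
        else:
            pos = int(site)
            if not p.start <= pos <= p.end:
                continue
            in_pep = pos - p.start + 1
            # a modified K at the peptide C-terminus implies an impossible
            # cleavage, unless it is the protein C-terminus
            if in_pep == len(p) and not p.is_protein_cterm:
                continue
            if len(p) < 3:
                continue
            cand = (p, in_pep)
        if best is None or (len(cand[0]), cand[0].missed_cleavages_K) < \
                (len(best[0]), best[0].missed_cleavages_K):
            best = cand
    if best is None:
        raise InputError(f"no tryptic peptide carries site {protein}:{site}")
    return best


def _base_rt(seq_a: str, seq_b: str) -> float:
    """Deterministic elution time in [20, 80] min from a sequence hash."""
    digest_ = hashlib.sha256(f"{min(seq_a, seq_b)}|{max(seq_a, seq_b)}"
                             .encode()).digest()
    frac = int.from_bytes(digest_[:4], "big") / 2 ** 32
    return 20.0 + 60.0 * frac


def simulate_spectra(truth: GroundTruth, *, fragment_efficiency: float = 0.7,
                     form_dropout: float = 0.05, noise_peaks: int = 30,
                     rt_jitter_sd: float = 0.05,
                     missing_form_prob: float = 0.0,
                     noise_spectra_per_true: int = 10,
                     seed: int = 0) -> GroundTruth:
    """Emit paired light/heavy MS2 spectra for every planted link, plus
    noise-only spectra.

    Per link: a candidate is built from tryptic peptides carrying the two
    sites; each theoretical b/y fragment (charges 1-2) is retained with
    probability ``fragment_efficiency``. Because the two isotopologues
    fragment near-identically, the retention mask is drawn once per link
    and shared between the light and heavy spectra; ``form_dropout`` is a
    small additional per-spectrum loss emulating scan-to-scan variation.
    Intensities are log-normal; ``noise_peaks`` uniform noise peaks are
    added; the pair shares a retention time up to Gaussian jitter, and the
    precursors differ by exactly the d12 shift (plus small, independent
    ppm-scale mass error). The heavy form is suppressed with probability
    ``missing_form_prob``.
    """
    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    emitted: dict[str, tuple[int, str, float]] = {}

    for li, link in enumerate(truth.true_links):
        pep_a, site_a = peptide_for_site(truth.proteins, *link.site_a)
        pep_b, site_b = peptide_for_site(truth.proteins, *link.site_b)
        charge = int(rng.choice([3, 4]))
        rt0 = _base_rt(pep_a.sequence, pep_b.sequence)
        drop_heavy = rng.random() < missing_form_prob
        all_labels = [f.label for f in generate_fragments(
            make_pair_candidate(pep_a, site_a, pep_b, site_b,
                                LinkerForm.LIGHT), max_charge=2,
            mz_range=(0.0, math.inf))]
        keep_base = {lbl: bool(v)
                     for lbl, v in zip(all_labels,
                                       rng.random(len(all_labels))
                                       < fragment_efficiency)}
        # isotopologues ionize and fragment alike: one intensity per
        # fragment, shared by the two forms up to a small jitter
        intensity_base = {
            lbl: float(v) for lbl, v in zip(
                all_labels,
                np.exp(rng.normal(math.log(1000.0), 0.5,
                                  size=len(all_labels))))}
        for form in (LinkerForm.LIGHT, LinkerForm.HEAVY):
            # draws below must stay in a fixed order for determinism
            rt = rt0 + float(rng.normal(0.0, rt_jitter_sd))
            ppm_err = float(rng.normal(0.0, 0.5))
            cand = make_pair_candidate(pep_a, site_a, pep_b, site_b, form)
            frags = generate_fragments(cand, max_charge=2)
            dropout = rng.random(len(frags)) >= form_dropout
            keep = [keep_base.get(f.label, False) and bool(d)
                    for f, d in zip(frags, dropout)]
            kept = [f for f, k in zip(frags, keep) if k]
            sig_mz = [f.theoretical_mz for f in kept]
            jitter = rng.normal(0.0, 0.1, size=len(kept))
            sig_int = np.array([
                intensity_base[f.label] * max(1.0 + j, 0.1)
                for f, j in zip(kept, jitter)])
            noise_mz = rng.uniform(150.0, 1900.0, size=noise_peaks)
            noise_int = np.exp(rng.normal(math.log(80.0), 0.7,
                                          size=noise_peaks))
            if form is LinkerForm.HEAVY and drop_heavy:
                continue
            mass = cand.precursor_mass * (1.0 + ppm_err * 1e-6)
            scan_id = f"link{li:03d}_{form.value}"
            spectra.append(Spectrum(
                scan_id=scan_id, precursor_neutral_mass=mass, charge=charge,
                retention_time=rt,
                mz=np.concatenate([sig_mz, noise_mz]),
                intensity=np.concatenate([sig_int, noise_int])))
            emitted[scan_id] = (li, form.value, rt)

    n_noise = noise_spectra_per_true * len(spectra)
    for i in range(n_noise):
        mass = float(rng.uniform(1000.0, 4500.0))
        charge = int(rng.choice([3, 4]))
        rt = float(rng.uniform(10.0, 110.0))
        mz = rng.uniform(150.0, 1900.0, size=2 * noise_peaks)
        inten = np.exp(rng.normal(math.log(150.0), 0.9, size=2 * noise_peaks))
        spectra.append(Spectrum(f"noise{i:04d}", mass, charge, rt, mz, inten))

    truth.spectra = spectra
    truth.emitted_spectra = emitted
    return truth


def true_link_ids(truth: GroundTruth) -> set[tuple]:
    """Residue-pair identifiers of the planted links, in the same
    convention as :func:`isoxl.pairing.link_id` (N-terminus -> residue 1)."""
    ids = set()
    for link in truth.true_links:
        def res_id(site):
            chain, pos = site
            return (chain, 1 if pos == NTERM else int(pos))
        ids.add(tuple(sorted((res_id(link.site_a), res_id(link.site_b)))))
    return ids


def make_fixture(outdir: str | Path, *, seed: int = 0, n_chains: int = 4,
                 chain_length: int = 50, n_links: int = 20,
                 frac_terminal: float = 0.9,
                 noise_spectra_per_true: int = 10,
                 missing_form_prob: float = 0.0) -> GroundTruth:
    """Generate and write the full fixture set: FASTA, PDB, MGF, and a
    ground-truth link TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db, model = make_toy_complex(seed, n_chains=n_chains,
                                 chain_length=chain_length)
    truth = plant_crosslinks(db, model, n_links,
                             frac_terminal=frac_terminal, seed=seed + 1)
    truth = simulate_spectra(truth, seed=seed + 2,
                             noise_spectra_per_true=noise_spectra_per_true,
                             missing_form_prob=missing_form_prob)
    write_fasta(db, outdir / "proteins.fasta")
    write_pdb(model, db, outdir / "complex.pdb")
    write_mgf(truth.spectra, outdir / "spectra.mgf")
    with open(outdir / "true_links.tsv", "w") as fh:
        fh.write("chain1\tsite1\tchain2\tsite2\txl_type\tsas\n")
        for link in truth.true_links:
            sas = "" if math.isnan(link.sas) else f"{link.sas:.2f}"
            fh.write(f"{link.site_a[0]}\t{link.site_a[1]}\t{link.site_b[0]}"
                     f"\t{link.site_b[1]}\t{link.xl_type}\t{sas}\n")
    return truth
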