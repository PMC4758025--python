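"""End-to-end workflow: digest -> cross-link search (target+decoy, light
and heavy) -> decoy-FDR thresholding -> isotope-pair validation ->
trypsin-consistency check -> optional structural filtering and hotspot
report. Every stage writes a TSV; a run log records the configuration,
seed, and per-stage counts so a report is self-describing.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .chem import LinkerForm
from .config import SearchConfig
from .digestion import (
    ProteinDB,
    digest_with_modifications,
    read_fasta,
    reverse_decoy,
)
from .pairing import (
    IsotopePairResult,
    link_id,
    pairs_to_table,
    validate_pairs,
)
from .search import (
    PSM,
    PeptideIndex,
    search_spectra,
    threshold_at_fdr,
    trypsin_consistency,
)
from .spectra import read_mgf
from .structure import NTERM, filter_crosslinks, hotspot_report, read_structure


@dataclass
class PipelineResult:
    config: SearchConfig
    n_spectra: int
    n_peptides: int
    thresholds: dict[str, float]
    psms: dict[str, list[PSM]]
    pairs: list[IsotopePairResult]
    pair_table: pd.DataFrame
    validated_links: pd.DataFrame
    unique_links: pd.DataFrame
    structure_check: pd.DataFrame | None = None
    hotspots: pd.DataFrame | None = None


def _psm_table(psms: list[PSM]) -> pd.DataFrame:
    rows = []
    for p in psms:
        c = p.candidate
        sa = c.site_residue("alpha")
        sb = (c.site_residue("beta")
              if c.beta is not None or c.xl_type == "intra-peptide-loop"
              else ("", "", ""))
        rows.append({
            "scan": p.scan_id,
            "protein1": c.alpha.protein_id,
            "protein2": c.beta.protein_id if c.beta is not None else "",
            "peptide1": c.alpha.sequence,
            "peptide2": c.beta.sequence if c.beta is not None else "",
            "site1": f"{sa[0]}:{sa[1]}:{sa[2]}",
            "site2": f"{sb[0]}:{sb[1]}:{sb[2]}" if sb[0] else "",
            "xl_type": c.xl_type,
            "linker_form": c.form.value,
            "score": round(p.score, 4),
            "precursor_ppm": round(p.precursor_error_ppm, 4),
            "rt_min": round(p.retention_time, 4),
            "decoy": p.is_decoy,
            "trypsin": trypsin_consistency(c),
        })
    return pd.DataFrame(rows)


def _site_for_structure(protein: str, pos: int,
                        chain_map: dict[str, str]) -> tuple[str, int | str]:
    chain = chain_map.get(protein, protein)
    return (chain, NTERM if pos == 1 else pos)


def run_pipeline(fasta: str | Path, mgf: str | Path,
                 structure: str | Path | None = None,
                 config: SearchConfig | None = None,
                 outdir: str | Path = "isoxl_out",
                 chain_map: dict[str, str] | None = None) -> PipelineResult:
    config = config or SearchConfig()
    chain_map = chain_map or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log.append(f"{stamp} {msg}")

    note(f"isoxl {__version__} pipeline start")
    for key, val in config.as_items():
        note(f"config {key} = {val}")

    target_db = read_fasta(fasta)
    decoy_db = reverse_decoy(target_db)
    combined = ProteinDB(list(target_db.entries) + list(decoy_db.entries))
    note(f"database: {len(target_db)} target + {len(decoy_db)} decoy proteins")

    peptides = digest_with_modifications(
        combined, max_missed_K=config.missed_K, max_missed_R=config.missed_R,
        max_mox=config.max_mox, mass_min=config.mass_min,
        mass_max=config.mass_max)
    index = PeptideIndex(peptides)
    note(f"digestion: {len(peptides)} peptide forms in the mass window")

    spectra = read_mgf(mgf)
    note(f"spectra: {len(spectra)} MS2 scans read")

    results = search_spectra(
        spectra, index, tol_ppm=config.precursor_tol_ppm,
        fragment_tol_da=config.fragment_tol_da, snr_min=config.snr_min,
        max_fragment_charge=config.max_fragment_charge,
        min_precursor_charge=config.min_precursor_charge,
        mz_range=(config.mz_min, config.mz_max))

    thresholds: dict[str, float] = {}
    accepted: dict[str, list[PSM]] = {}
    for form in (LinkerForm.LIGHT, LinkerForm.HEAVY):
        psms = results[form]
        targets = [p for p in psms if not p.is_decoy]
        decoys = [p for p in psms if p.is_decoy]
        thr = threshold_at_fdr(targets, decoys, config.fdr_target)
        thresholds[form.value] = thr
        accepted[form.value] = [p for p in psms if p.score >= thr]
        note(f"search[{form.value}]: {len(targets)} target / {len(decoys)} "
             f"decoy PSMs; score threshold {thr:.3f} at FDR "
             f"<= {config.fdr_target}")
        _psm_table(psms).to_csv(outdir / f"psms_{form.value}.tsv", sep="\t",
                                index=False)

    pairs, unpaired = validate_pairs(
        accepted["light"], accepted["heavy"],
        mass_tol_ppm=config.pair_mass_tol_ppm, rt_tol_min=config.rt_tol_min,
        similarity_min=config.similarity_min)
    pair_table = pairs_to_table(pairs)
    pair_table.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    with open(outdir / "unpaired.tsv", "w") as fh:
        fh.write("scan\tlinker_form\treason\n")
        for psm, reason in unpaired:
            fh.write(f"{psm.scan_id}\t{psm.candidate.form.value}\t{reason}\n")
    note(f"pair validation: {len(pairs)} light/heavy pairs, "
         f"{len(unpaired)} unpaired PSMs")

    if pair_table.empty:
        validated = pair_table
    else:
        validated = pair_table[
            (pair_table.verdict == "validated")
            & (pair_table.trypsin == "consistent")].reset_index(drop=True)
    validated.to_csv(outdir / "validated_links.tsv", sep="\t", index=False)
    note(f"validated cross-link peptides: {len(validated)} "
         f"({int(validated.decoy.sum()) if not validated.empty else 0} decoy)")

    # collapse redundant peptide identifications to unique residue pairs
    unique_rows = []
    seen: dict[tuple, dict] = {}
    validated_pairs = [p for p in pairs
                       if p.verdict == "validated"
                       and trypsin_consistency(p.light.candidate)
                       == "consistent"]
    for p in validated_pairs:
        lid = link_id(p)
        entry = seen.setdefault(lid, {
            "protein1": lid[0][0], "site1": lid[0][1],
            "protein2": lid[1][0], "site2": lid[1][1],
            "xl_type": lid[2], "n_peptide_pairs": 0, "best_score": 0.0,
            "decoy": False})
        entry["n_peptide_pairs"] += 1
        entry["best_score"] = max(entry["best_score"],
                                  round(min(p.light.score, p.heavy.score), 4))
        entry["decoy"] |= p.light.is_decoy or p.heavy.is_decoy
    unique_rows = [seen[k] for k in sorted(seen)]
    unique_links = pd.DataFrame(unique_rows)
    unique_links.to_csv(outdir / "unique_links.tsv", sep="\t", index=False)
    note(f"unique residue-pair links: {len(unique_links)}")

    structure_check = hotspots = None
    if structure is not None:
        model = read_structure(structure)
        site_pairs = [
            (_site_for_structure(r["protein1"], r["site1"], chain_map),
             _site_for_structure(r["protein2"], r["site2"], chain_map))
            for r in unique_rows if not r["decoy"]]
        dist = filter_crosslinks(site_pairs, model, cutoff=config.sas_cutoff,
                                 grid_spacing=config.grid_spacing,
                                 probe_radius=config.probe_radius)
        structure_check = pd.DataFrame([{
            "chain1": d.site_a[0], "site1": d.site_a[1],
            "chain2": d.site_b[0], "site2": d.site_b[1],
            "euclidean_A": round(d.euclidean, 2)
            if math.isfinite(d.euclidean) else "",
            "sas_A": round(d.sas, 2) if math.isfinite(d.sas) else "",
            "slack_A": d.slack, "within_cutoff": d.within_cutoff,
        } for d in dist])
        structure_check.to_csv(outdir / "structure_check.tsv", sep="\t",
                               index=False)
        hotspots = hotspot_report(site_pairs, model)
        hotspots.to_csv(outdir / "hotspots.tsv", sep="\t", index=False)
        n_fail = sum(d.within_cutoff == "fail" for d in dist)
        n_unc = sum(d.within_cutoff == "unconstrained" for d in dist)
        note(f"structure check: {len(dist)} links, {n_fail} beyond "
             f"{config.sas_cutoff} A, {n_unc} unconstrained (unresolved site)")

    note("pipeline done")
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")

    return PipelineResult(
        config=config, n_spectra=len(spectra), n_peptides=len(peptides),
        thresholds=thresholds, psms=accepted, pairs=pairs,
        pair_table=pair_table, validated_links=validated,
        unique_links=unique_links, structure_check=structure_check,
        hotspots=hotspots)
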