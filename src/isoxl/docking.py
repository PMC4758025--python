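"""CAPRI-style assessment of docking models against a reference complex.

Quality of a predicted receptor-ligand arrangement is summarized by fnat
(fraction of native residue-residue contacts reproduced), ligand RMSD
(ligand backbone after superposing on the receptor backbone) and
interface RMSD (backbone of reference interface residues after
superposing on them), combined into the standard four CAPRI classes.

All thresholds live in one constants block below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chem import InputError
from .structure import StructureModel

# -- CAPRI convention (single source of truth) ------------------------------
CONTACT_CUTOFF = 5.0          # A, heavy-atom residue-residue contact
INTERFACE_CUTOFF = 10.0       # A, residues defining the interface for i-RMSD
BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: (min fnat, max L-RMSD, max i-RMSD) per class, tested in order
CAPRI_CLASSES = (
    ("high", 0.5, 1.0, 1.0),
    ("medium", 0.3, 5.0, 2.0),
    ("acceptable", 0.1, 10.0, 4.0),
)


def _chain_atoms(model: StructureModel, chains: list[str]
                 ) -> tuple[np.ndarray, list[tuple[str, int]]]:
    coords, owners = [], []
    for cid in chains:
        if cid not in model.chains:
            raise InputError(f"chain {cid!r} not in structure")
        for res in model.chains[cid]:
            for atom in res.atoms.values():
                if atom.element != "H":
                    coords.append(atom.pos)
                    owners.append((cid, res.seqid))
    if not coords:
        raise InputError(f"chains {chains} contain no atoms")
    return np.array(coords), owners


def native_contacts(model: StructureModel, receptor_chains: list[str],
                    ligand_chains: list[str], cutoff: float = CONTACT_CUTOFF
                    ) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """All (receptor residue, ligand residue) pairs with any heavy-atom
    pair within ``cutoff``."""
    rc, ro = _chain_atoms(model, receptor_chains)
    lc, lo = _chain_atoms(model, ligand_chains)
    pairs = cKDTree(rc).query_ball_tree(cKDTree(lc), cutoff)
    out = set()
    for i, hits in enumerate(pairs):
        for j in hits:
            out.add((ro[i], lo[j]))
    return out


def fnat(model: StructureModel, reference: StructureModel,
         receptor_chains: list[str], ligand_chains: list[str],
         cutoff: float = CONTACT_CUTOFF) -> float:
    ref = native_contacts(reference, receptor_chains, ligand_chains, cutoff)
    if not ref:
        raise InputError("reference complex has no interface contacts; "
                         "fnat undefined")
    mod = native_contacts(model, receptor_chains, ligand_chains, cutoff)
    return len(mod & ref) / len(ref)


def interface_recall(model: StructureModel, reference: StructureModel,
                     receptor_chains: list[str], ligand_chains: list[str],
                     cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of reference interface *residues* recovered by the model
    (reported alongside fnat, which counts contacts)."""
    def residues(contacts):
        return {r for pair in contacts for r in pair}
    ref = residues(native_contacts(reference, receptor_chains,
                                   ligand_chains, cutoff))
    if not ref:
        raise InputError("reference complex has no interface residues")
    mod = residues(native_contacts(model, receptor_chains, ligand_chains,
                                   cutoff))
    return len(mod & ref) / len(ref)


def superpose(mobile: np.ndarray, target: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch, det +1 enforced).

    Returns (rotation, translation, rmsd) such that
    ``mobile @ R.T + t`` approximates ``target``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError("coordinate arrays must be matching (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise InputError("need at least 3 paired points")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10:
        raise InputError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = tc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rot, trans, rmsd


def _paired_backbone(model: StructureModel, reference: StructureModel,
                     chains: list[str],
                     residue_filter: set[tuple[str, int]] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    mob, tgt, missing = [], [], []
    for cid in chains:
        if cid not in reference.chains:
            raise InputError(f"chain {cid!r} not in reference")
        if cid not in model.chains:
            raise InputError(f"chain {cid!r} not in model")
        for ref_res in reference.chains[cid]:
            if not ref_res.resolved:
                continue
            if (residue_filter is not None
                    and (cid, ref_res.seqid) not in residue_filter):
                continue
            mod_res = model.residue(cid, ref_res.seqid)
            if mod_res is None or not mod_res.resolved:
                missing.append((cid, ref_res.seqid))
                continue
            for name in BACKBONE_ATOMS:
                if name in ref_res.atoms and name in mod_res.atoms:
                    tgt.append(ref_res.atoms[name].pos)
                    mob.append(mod_res.atoms[name].pos)
    if missing:
        warnings.warn(f"{len(missing)} residues missing from the model "
                      f"dropped from the correspondence: {missing[:5]}...")
    if not mob:
        raise InputError(f"no paired backbone atoms for chains {chains}")
    return np.array(mob), np.array(tgt)


def ligand_rmsd(model: StructureModel, reference: StructureModel,
                receptor_chains: list[str], ligand_chains: list[str]
                ) -> float:
    """Ligand backbone RMSD after superposing on the receptor backbone
    (no further fitting of the ligand)."""
    mob_r, tgt_r = _paired_backbone(model, reference, receptor_chains)
    rot, trans, _ = superpose(mob_r, tgt_r)
    mob_l, tgt_l = _paired_backbone(model, reference, ligand_chains)
    moved = mob_l @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((moved - tgt_l) ** 2, axis=1))))


def interface_rmsd(model: StructureModel, reference: StructureModel,
                   receptor_chains: list[str], ligand_chains: list[str],
                   cutoff: float = INTERFACE_CUTOFF) -> float:
    """Backbone RMSD over reference interface residues after superposing
    on those same residues."""
    contacts = native_contacts(reference, receptor_chains, ligand_chains,
                               cutoff)
    iface = {r for pair in contacts for r in pair}
    if not iface:
        raise InputError("reference complex has no interface residues")
    mob, tgt = _paired_backbone(model, reference,
                                receptor_chains + ligand_chains,
                                residue_filter=iface)
    _, _, rmsd = superpose(mob, tgt)
    return rmsd


def capri_class(fnat_value: float, ligand_rmsd_value: float,
                interface_rmsd_value: float) -> str:
    """Standard CAPRI quality classes from (fnat, L-RMSD, i-RMSD)."""
    for name, min_fnat, max_l, max_i in CAPRI_CLASSES:
        if fnat_value >= min_fnat and (ligand_rmsd_value <= max_l
                                       or interface_rmsd_value <= max_i):
            return name
    return "incorrect"


@dataclass
class DockAssessment:
    model_id: str
    fnat: float
    ligand_rmsd: float
    interface_rmsd: float
    interface_recall: float
    quality: str


def assess_model(model: StructureModel, reference: StructureModel,
                 receptor_chains: list[str], ligand_chains: list[str],
                 model_id: str = "model") -> DockAssessment:
    f = fnat(model, reference, receptor_chains, ligand_chains)
    lr = ligand_rmsd(model, reference, receptor_chains, ligand_chains)
    ir = interface_rmsd(model, reference, receptor_chains, ligand_chains)
    rec = interface_recall(model, reference, receptor_chains, ligand_chains)
    return DockAssessment(model_id, f, lr, ir, rec, capri_class(f, lr, ir))
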