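"""Structure-based plausibility filtering of cross-links.

Distances between reactive atoms are measured two ways: straight-line
Euclidean, and solvent-accessible-surface (SAS) distance — the shortest
path through solvent between the two atoms, around the protein body —
computed by uniform-cost search on a 3-D occupancy grid. Cross-links are
compared against a maximum-reach cutoff (default 35 A for BS3: 11.4 A
spacer + two lysine side chains + conformational slack).

Sites that are unresolved in the crystal structure (typically flexible
termini) yield "unconstrained", never pass/fail: an unresolved site
carries no geometric information.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .chem import InputError
from .constants import REACTIVE_ATOMS, VDW_DEFAULT, VDW_RADII

#: extra reach granted when a side-chain reactive atom is absent and a
#: CB/CA fallback is used instead
FALLBACK_SLACK = 3.0

NTERM = "nterm"


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    b_factor: float

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element, VDW_DEFAULT)


@dataclass
class Residue:
    chain: str
    seqid: int
    name: str
    resolved: bool
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def mean_b(self) -> float:
        if not self.atoms:
            return math.nan
        return float(np.mean([a.b_factor for a in self.atoms.values()]))


@dataclass
class StructureModel:
    chains: dict[str, list[Residue]]

    def residue(self, chain: str, seqid: int) -> Residue | None:
        for r in self.chains.get(chain, []):
            if r.seqid == seqid:
                return r
        return None

    def first_residue(self, chain: str) -> Residue | None:
        residues = self.chains.get(chain, [])
        return residues[0] if residues else None

    def heavy_atoms(self, exclude: set[tuple[str, int]] = frozenset()
                    ) -> list[Atom]:
        out = []
        for cid, residues in self.chains.items():
            for r in residues:
                if (cid, r.seqid) in exclude:
                    continue
                out.extend(a for a in r.atoms.values() if a.element != "H")
        return out


def read_structure(path: str | Path) -> StructureModel:
    """Read PDB or mmCIF; residues present in the full (SEQRES/entity)
    sequence but lacking atoms are flagged unresolved."""
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"cannot parse structure file {path}: {exc}") from None
    if len(st) == 0:
        raise InputError(f"no models in structure file {path}")
    st.setup_entities()
    st.assign_label_seq_id()
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        present: dict[int, Residue] = {}
        for res in chain:
            atoms = {
                a.name: Atom(a.name, a.element.name.upper(),
                             np.array([a.pos.x, a.pos.y, a.pos.z]),
                             a.b_iso)
                for a in res
            }
            r = Residue(chain.name, res.seqid.num, res.name, True, atoms)
            present[res.seqid.num] = r
        # expected residues from the entity (SEQRES) sequence, assuming
        # author numbering 1..N aligned with the full sequence
        polymer = chain.get_polymer()
        ent = st.get_entity_of(polymer)
        full = list(ent.full_sequence) if ent is not None else []
        if full and len(full) >= len(present):
            for i, mon in enumerate(full, start=1):
                name = gemmi.Entity.first_mon(mon)
                if i in present:
                    residues.append(present[i])
                else:
                    residues.append(Residue(chain.name, i, name, False))
            # residues observed outside the SEQRES range (rare) kept too
            for num in sorted(present):
                if num > len(full) or num < 1:
                    residues.append(present[num])
        else:
            residues = [present[num] for num in sorted(present)]
        chains[chain.name] = residues
    if not any(chains.values()):
        raise InputError(f"structure file {path} contains no residues")
    return StructureModel(chains)


@dataclass
class AtomRef:
    chain: str
    seqid: int
    atom: str
    pos: np.ndarray
    slack: float = 0.0


def reactive_atom(model: StructureModel, chain: str,
                  site: int | str) -> AtomRef | None:
    """Reactive atom of a cross-link site; None when unconstrained.

    K -> NZ, protein N-terminus -> backbone N, S -> OG, T -> OG1,
    Y -> OH. If the side-chain atom is missing from a resolved residue,
    falls back to CB (then CA) with a recorded 3 A slack.
    """
    if site == NTERM:
        res = model.first_residue(chain)
        if res is None:
            raise InputError(f"unknown chain {chain!r}")
        preferred = "N"
    else:
        res = model.residue(chain, int(site))
        if res is None:
            if chain not in model.chains:
                raise InputError(f"unknown chain {chain!r}")
            return None
        preferred = REACTIVE_ATOMS.get(res.name, "CA")
    if not res.resolved:
        return None
    for name, slack in ((preferred, 0.0), ("CB", FALLBACK_SLACK),
                        ("CA", FALLBACK_SLACK)):
        if name in res.atoms:
            return AtomRef(chain, res.seqid, name, res.atoms[name].pos, slack)
    return None


def euclidean_distance(a: AtomRef | np.ndarray, b: AtomRef | np.ndarray
                       ) -> float:
    pa = a.pos if isinstance(a, AtomRef) else np.asarray(a, float)
    pb = b.pos if isinstance(b, AtomRef) else np.asarray(b, float)
    return float(np.linalg.norm(pa - pb))


_NEIGHBORS = [np.array(d) for d in itertools.product((-1, 0, 1), repeat=3)
              if d != (0, 0, 0)]
_NEIGHBOR_COSTS = [float(np.linalg.norm(d)) for d in _NEIGHBORS]


def _blocked_grid(atoms: list[Atom], origin: np.ndarray, shape: tuple,
                  spacing: float, probe_radius: float) -> np.ndarray:
    blocked = np.zeros(shape, dtype=bool)
    axes = [np.arange(n) * spacing + origin[k] for k, n in enumerate(shape)]
    for atom in atoms:
        r = atom.vdw_radius + probe_radius
        lo_idx = np.maximum(np.floor((atom.pos - r - origin) / spacing), 0
                            ).astype(int)
        hi_idx = np.minimum(np.ceil((atom.pos + r - origin) / spacing),
                            np.array(shape) - 1).astype(int)
        if np.any(lo_idx > hi_idx):
            continue
        sub = [axes[k][lo_idx[k]:hi_idx[k] + 1] - atom.pos[k]
               for k in range(3)]
        d2 = (sub[0][:, None, None] ** 2 + sub[1][None, :, None] ** 2
              + sub[2][None, None, :] ** 2)
        region = blocked[lo_idx[0]:hi_idx[0] + 1, lo_idx[1]:hi_idx[1] + 1,
                         lo_idx[2]:hi_idx[2] + 1]
        region |= d2 <= r * r
    return blocked


def _snap(point: np.ndarray, blocked: np.ndarray, origin: np.ndarray,
          spacing: float) -> tuple[tuple[int, int, int] | None, float]:
    """Nearest free cell within 2x spacing of the point."""
    center = np.round((point - origin) / spacing).astype(int)
    reach = int(math.ceil(2.0 / 1.0)) + 1   # cells within 2*spacing
    best, best_d = None, math.inf
    shape = blocked.shape
    for off in itertools.product(range(-reach, reach + 1), repeat=3):
        idx = center + np.array(off)
        if np.any(idx < 0) or np.any(idx >= shape):
            continue
        if blocked[tuple(idx)]:
            continue
        cell_pos = origin + idx * spacing
        d = float(np.linalg.norm(cell_pos - point))
        if d <= 2.0 * spacing and d < best_d:
            best, best_d = tuple(int(v) for v in idx), d
    return best, best_d


def sas_distance(model: StructureModel, a: AtomRef, b: AtomRef, *,
                 grid_spacing: float = 1.0, probe_radius: float = 1.4,
                 margin: float = 70.0, max_path: float | None = None,
                 ) -> float:
    """Solvent-accessible-surface distance between two reactive atoms.

    A grid over the endpoints' bounding box (+ ``margin``) marks cells
    within (vdW + probe) of any heavy atom as blocked; atoms of the two
    query residues are left unblocked. The shortest 26-connected path is
    found by uniform-cost search (step costs {1, sqrt2, sqrt3} x spacing);
    endpoints snap to the nearest free cell, with the snap offsets added.
    Returns ``inf`` when no free path exists (or when ``max_path`` is
    exceeded, which callers use to decide a pass/fail cutoff cheaply).
    """
    exclude = {(a.chain, a.seqid), (b.chain, b.seqid)}
    atoms = model.heavy_atoms(exclude=exclude)
    lo = np.minimum(a.pos, b.pos) - margin
    hi = np.maximum(a.pos, b.pos) + margin
    shape = tuple(int(math.ceil((hi[k] - lo[k]) / grid_spacing)) + 1
                  for k in range(3))
    blocked = _blocked_grid(atoms, lo, shape, grid_spacing, probe_radius)

    start, snap_a = _snap(a.pos, blocked, lo, grid_spacing)
    goal, snap_b = _snap(b.pos, blocked, lo, grid_spacing)
    if start is None or goal is None:
        return math.inf      # endpoint buried
    if start == goal:
        return snap_a + snap_b

    cap = max_path if max_path is not None else math.inf
    dist = {start: 0.0}
    heap = [(0.0, start)]
    neighbors = [tuple(int(v) for v in d) for d in _NEIGHBORS]
    while heap:
        d, cell = heapq.heappop(heap)
        if d > dist.get(cell, math.inf):
            continue
        if cell == goal:
            return snap_a + d * grid_spacing + snap_b
        if d * grid_spacing > cap:
            return math.inf
        for off, cost in zip(neighbors, _NEIGHBOR_COSTS):
            nxt = (cell[0] + off[0], cell[1] + off[1], cell[2] + off[2])
            if not (0 <= nxt[0] < shape[0] and 0 <= nxt[1] < shape[1]
                    and 0 <= nxt[2] < shape[2]):
                continue
            if blocked[nxt]:
                continue
            nd = d + cost
            if nd < dist.get(nxt, math.inf):
                dist[nxt] = nd
                heapq.heappush(heap, (nd, nxt))
    return math.inf


@dataclass
class DistanceResult:
    site_a: tuple[str, int | str, str]      # (chain, residue or 'nterm', atom)
    site_b: tuple[str, int | str, str]
    euclidean: float
    sas: float
    within_cutoff: str                      # 'pass' | 'fail' | 'unconstrained'
    slack: float = 0.0


def filter_crosslinks(links: list[tuple[tuple[str, int | str],
                                        tuple[str, int | str]]],
                      model: StructureModel, *, cutoff: float = 35.0,
                      grid_spacing: float = 1.0, probe_radius: float = 1.4,
                      ) -> list[DistanceResult]:
    """Check each (chain, site) pair against the SAS cutoff.

    Links with an unresolved site are 'unconstrained' — the structure
    carries no information about them (the flexible-termini situation) —
    and are never counted as contradictions.
    """
    results = []
    for (ca, sa), (cb, sb) in links:
        ra = reactive_atom(model, ca, sa)
        rb = reactive_atom(model, cb, sb)
        if ra is None or rb is None:
            results.append(DistanceResult(
                (ca, sa, "-"), (cb, sb, "-"), math.nan, math.nan,
                "unconstrained"))
            continue
        slack = ra.slack + rb.slack
        eu = euclidean_distance(ra, rb)
        limit = cutoff + slack
        sas = sas_distance(model, ra, rb, grid_spacing=grid_spacing,
                           probe_radius=probe_radius,
                           max_path=limit + 3 * grid_spacing)
        status = "pass" if sas <= limit else "fail"
        results.append(DistanceResult((ca, sa, ra.atom), (cb, sb, rb.atom),
                                      eu, sas, status, slack))
    return results


def hotspot_report(links: list[tuple[tuple[str, int | str],
                                     tuple[str, int | str]]],
                   model: StructureModel | None = None) -> pd.DataFrame:
    """Per-site cross-link counts, sorted descending — flexible, exposed
    sites (typically N-termini) accumulate many links."""
    counts: dict[tuple[str, int | str], int] = {}
    for pair in links:
        for site in pair:
            counts[site] = counts.get(site, 0) + 1
    rows = []
    for (chain, site), n in counts.items():
        resolved = None
        mean_b = math.nan
        if model is not None:
            res = (model.first_residue(chain) if site == NTERM
                   else model.residue(chain, int(site)))
            if res is not None:
                resolved = res.resolved
                if res.resolved:
                    mean_b = res.mean_b
                else:
                    # nearest resolved residue in the chain
                    cands = [r for r in model.chains[chain] if r.resolved]
                    anchor = (res.seqid if site != NTERM else 1)
                    if cands:
                        nearest = min(cands,
                                      key=lambda r: abs(r.seqid - anchor))
                        mean_b = nearest.mean_b
        rows.append({"chain": chain, "site": site,
                     "is_nterm": site == NTERM, "n_links": n,
                     "resolved": resolved, "mean_b_factor":
                     round(mean_b, 3) if not math.isnan(mean_b) else math.nan})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["n_links", "chain", "site"],
                            ascending=[False, True, True],
                            key=lambda s: s.astype(str) if s.name == "site"
                            else s).reset_index(drop=True)
    return df
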