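"""Structure parsing, reactive atoms, Euclidean and solvent-accessible
surface distances (vs. an independent graph-search oracle), cutoff
filtering, and hotspot reporting."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from isoxl.chem import InputError
from isoxl.structure import (
    NTERM,
    AtomRef,
    euclidean_distance,
    filter_crosslinks,
    hotspot_report,
    reactive_atom,
    read_structure,
    sas_distance,
)

PDB_3RES = """\
ATOM      1  N   LYS A   1       0.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA  LYS A   1       1.458   0.000   0.000  1.00 20.00           C
ATOM      3  NZ  LYS A   1       3.000   2.000   1.000  1.00 30.00           N
ATOM      4  CA  SER A   2       4.000   0.500   0.000  1.00 21.00           C
ATOM      5  OG  SER A   2       4.800   1.900   0.700  1.00 22.00           O
ATOM      6  CA  GLY A   3       7.500   1.000   0.000  1.00 23.00           C
END
"""


def write_pdb_with_seqres(path, n_seqres=10, present=range(4, 11),
                          spacing=4.0):
    """CA-only lysine chain along x; residues outside ``present`` appear
    in SEQRES but have no atoms (unresolved)."""
    lines = [f"SEQRES   1 A   {n_seqres:2d}  " + " ".join(["LYS"] * n_seqres)]
    for serial, i in enumerate(present, start=1):
        lines.append(
            f"ATOM  {serial:5d}  CA  LYS A{i:4d}    "
            f"{i * spacing:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{20.0:6.2f}"
            f"           C")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


class TestReadStructure:
    def test_three_resolved_residues(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(PDB_3RES)
        model = read_structure(path)
        residues = model.chains["A"]
        assert len(residues) == 3
        assert all(r.resolved for r in residues)
        assert residues[0].name == "LYS" and "NZ" in residues[0].atoms

    def test_seqres_gap_counts_unresolved(self, tmp_path):
        path = tmp_path / "gap.pdb"
        write_pdb_with_seqres(path)
        model = read_structure(path)
        unresolved = [r for r in model.chains["A"] if not r.resolved]
        assert len(unresolved) == 3
        assert [r.seqid for r in unresolved] == [1, 2, 3]
        assert all(not r.atoms for r in unresolved)

    def test_empty_file_is_input_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(InputError):
            read_structure(path)


class TestReactiveAtom:
    def test_lysine_uses_nz(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(PDB_3RES)
        model = read_structure(path)
        ref = reactive_atom(model, "A", 1)
        assert (ref.atom, ref.slack) == ("NZ", 0.0)
        assert reactive_atom(model, "A", 2).atom == "OG"

    def test_truncated_side_chain_falls_back_with_slack(self, tmp_path):
        path = tmp_path / "gap.pdb"
        write_pdb_with_seqres(path)
        model = read_structure(path)
        ref = reactive_atom(model, "A", 5)      # CA-only residue
        assert (ref.atom, ref.slack) == ("CA", 3.0)

    def test_unresolved_nterm_is_unconstrained(self, tmp_path):
        path = tmp_path / "gap.pdb"
        write_pdb_with_seqres(path)
        model = read_structure(path)
        assert reactive_atom(model, "A", NTERM) is None

    def test_unknown_chain_is_input_error(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(PDB_3RES)
        with pytest.raises(InputError):
            reactive_atom(read_structure(path), "Z", NTERM)


class TestEuclidean:
    def test_345_triangle(self):
        a = AtomRef("A", 1, "NZ", np.array([0.0, 0.0, 0.0]))
        b = AtomRef("A", 2, "NZ", np.array([3.0, 4.0, 0.0]))
        assert euclidean_distance(a, b) == pytest.approx(5.0)
        assert euclidean_distance(a, a) == 0.0


def _wall_model(make_structure, height=8.0, spacing=1.5):
    """A slab of carbon atoms in the x=5 plane blocking the direct path."""
    atoms = []
    coords = [(5.0, y, z)
              for y in np.arange(-height, height + 0.1, spacing)
              for z in np.arange(-height, height + 0.1, spacing)]
    residues = [(100 + i, "GLY", {"CA": c}) for i, c in enumerate(coords)]
    return make_structure({"W": residues})


def oracle_grid_path(model, a, b, margin, spacing=1.0, probe=1.4):
    """Independent SAS-path oracle: explicit grid + networkx Dijkstra."""
    atoms = [(atom.pos, atom.vdw_radius) for atom in model.heavy_atoms(
        exclude={(a.chain, a.seqid), (b.chain, b.seqid)})]
    lo = np.minimum(a.pos, b.pos) - margin
    hi = np.maximum(a.pos, b.pos) + margin
    shape = tuple(int(math.ceil((hi[k] - lo[k]) / spacing)) + 1
                  for k in range(3))
    def blocked(idx):
        center = lo + np.array(idx) * spacing
        return any(np.linalg.norm(center - pos) <= r + probe
                   for pos, r in atoms)
    free = {idx for idx in itertools.product(*(range(n) for n in shape))
            if not blocked(idx)}
    def snap(point):
        best, best_d = None, math.inf
        for idx in free:
            d = float(np.linalg.norm(lo + np.array(idx) * spacing - point))
            if d <= 2 * spacing and d < best_d:
                best, best_d = idx, d
        return best, best_d
    start, da = snap(a.pos)
    goal, db = snap(b.pos)
    if start is None or goal is None:
        return math.inf
    g = nx.Graph()
    for idx in free:
        for off in itertools.product((-1, 0, 1), repeat=3):
            if off == (0, 0, 0):
                continue
            nbr = tuple(np.array(idx) + off)
            if nbr in free:
                g.add_edge(idx, nbr,
                           weight=float(np.linalg.norm(off)) * spacing)
    try:
        path = nx.dijkstra_path_length(g, start, goal)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return math.inf
    return da + path + db


class TestSasDistance:
    def test_open_space_close_to_euclidean(self, make_structure):
        model = make_structure({})
        a = AtomRef("A", 1, "NZ", np.array([0.0, 0.0, 0.0]))
        b = AtomRef("A", 2, "NZ", np.array([10.0, 0.0, 0.0]))
        d = sas_distance(model, a, b, margin=6.0)
        assert 10.0 <= d <= 11.0        # 26-connectivity overestimates <=10%

    def test_wall_detour_equals_graph_oracle(self, make_structure):
        model = _wall_model(make_structure)
        a = AtomRef("A", 1, "NZ", np.array([0.0, 0.0, 0.0]))
        b = AtomRef("A", 2, "NZ", np.array([10.0, 0.0, 0.0]))
        got = sas_distance(model, a, b, margin=12.0)
        want = oracle_grid_path(model, a, b, margin=12.0)
        assert got > 10.0               # must detour around the slab
        assert got == pytest.approx(want, abs=1e-9)

    def test_buried_endpoint_unreachable(self, make_structure):
        shell = [(x, y, z) for x in (-2.5, 0, 2.5) for y in (-2.5, 0, 2.5)
                 for z in (-2.5, 0, 2.5) if (x, y, z) != (0, 0, 0)]
        model = make_structure(
            {"B": [(100 + i, "GLY", {"CA": c}) for i, c in enumerate(shell)]})
        a = AtomRef("A", 1, "NZ", np.array([0.0, 0.0, 0.0]))
        b = AtomRef("A", 2, "NZ", np.array([12.0, 0.0, 0.0]))
        assert sas_distance(model, a, b, margin=8.0) == math.inf

    def test_symmetric_and_at_least_euclidean(self, make_structure):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-6, 6, size=(25, 3))
        model = make_structure(
            {"R": [(100 + i, "GLY", {"CA": tuple(c)})
                   for i, c in enumerate(coords)]})
        for _ in range(4):
            pa = rng.uniform(-9, 9, size=3)
            pb = rng.uniform(-9, 9, size=3)
            a = AtomRef("A", 1, "NZ", pa)
            b = AtomRef("A", 2, "NZ", pb)
            d_ab = sas_distance(model, a, b, margin=8.0)
            d_ba = sas_distance(model, b, a, margin=8.0)
            assert d_ab == pytest.approx(d_ba, abs=1e-9)
            if math.isfinite(d_ab):
                assert d_ab >= euclidean_distance(a, b) - 1e-9


class TestFilterCrosslinks:
    def test_cutoff_pass_fail_and_unconstrained(self, tmp_path,
                                                make_structure):
        path = tmp_path / "gap.pdb"
        write_pdb_with_seqres(path, present=range(4, 11))
        model = read_structure(path)
        links = [
            (("A", 4), ("A", 10)),       # resolved pair, ~6 A apart
            (("A", NTERM), ("A", 10)),   # N-terminus unresolved
        ]
        results = filter_crosslinks(links, model, cutoff=35.0)
        assert results[0].within_cutoff == "pass"
        assert results[0].sas >= results[0].euclidean - 1e-9
        assert results[1].within_cutoff == "unconstrained"

    def test_link_beyond_cutoff_fails(self, tmp_path):
        path = tmp_path / "far.pdb"
        lines = []
        for serial, (num, x) in enumerate([(1, 0.0), (2, 50.0)], start=1):
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA A{num:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{20.0:6.2f}"
                f"           C")
        path.write_text("\n".join(lines) + "\nEND\n")
        model = read_structure(path)
        [res] = filter_crosslinks([(("A", 1), ("A", 2))], model, cutoff=35.0)
        assert res.within_cutoff == "fail"

    def test_cutoff_monotonicity(self, tmp_path):
        path = tmp_path / "gap.pdb"
        write_pdb_with_seqres(path, present=range(1, 11))
        model = read_structure(path)
        links = [(("A", i), ("A", j))
                 for i in (1, 3, 5) for j in (7, 9, 10)]
        pass30 = {i for i, r in enumerate(
            filter_crosslinks(links, model, cutoff=30.0))
            if r.within_cutoff == "pass"}
        pass35 = {i for i, r in enumerate(
            filter_crosslinks(links, model, cutoff=35.0))
            if r.within_cutoff == "pass"}
        assert pass30 <= pass35


class TestHotspotReport:
    def test_shared_site_counted(self):
        hub = ("B", NTERM)
        links = [(hub, ("A", 5)), (hub, ("A", 9)), (hub, ("C", 2))]
        df = hotspot_report(links)
        top = df.iloc[0]
        assert (top["chain"], top["site"], top["n_links"]) == ("B", NTERM, 3)
        assert top["is_nterm"]

    def test_no_links_empty_table(self):
        assert hotspot_report([]).empty

    def test_planted_hub_ranked_first(self):
        hub = ("A", 7)
        links = [(hub, ("B", i)) for i in (1, 2, 3, 4)]
        links += [(("C", 9), ("D", 1)), (("C", 9), ("D", 2))]
        df = hotspot_report(links)
        assert (df.iloc[0]["chain"], df.iloc[0]["site"]) == ("A", 7)
        assert df.iloc[0]["n_links"] == 4
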