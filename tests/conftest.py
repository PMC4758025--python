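"""Shared fixtures: synthetic complexes, spectra, and structure builders.

Expensive end-to-end fixtures are session-scoped so the planted-link
recovery checks reuse one simulated dataset.
"""

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isoxl.config import SearchConfig
from isoxl.pipeline import run_pipeline
from isoxl.simulate import make_fixture
from isoxl.structure import Atom, Residue, StructureModel

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: canonical seed for the synthetic study conditions
FIXTURE_SEED = 42


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A compact simulated run: 6 planted links, light noise load."""
    outdir = tmp_path_factory.mktemp("small_fixture")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        truth = make_fixture(outdir, seed=7, n_links=6,
                             noise_spectra_per_true=2)
    return outdir, truth


@pytest.fixture(scope="session")
def full_fixture(tmp_path_factory):
    """The full study-condition fixture: 20 planted links, 10 noise
    spectra per true spectrum, 90% involving a protein N-terminus."""
    outdir = tmp_path_factory.mktemp("full_fixture")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        truth = make_fixture(outdir, seed=FIXTURE_SEED, n_links=20,
                             noise_spectra_per_true=10)
    return outdir, truth


@pytest.fixture(scope="session")
def full_pipeline_run(full_fixture, tmp_path_factory):
    outdir, truth = full_fixture
    run_dir = tmp_path_factory.mktemp("full_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(outdir / "proteins.fasta",
                              outdir / "spectra.mgf",
                              outdir / "complex.pdb",
                              SearchConfig(), run_dir)
    return truth, result, run_dir


def build_model(chain_atoms: dict) -> StructureModel:
    """StructureModel from {chain: [(seqid, resname, {atom: xyz}), ...]}."""
    chains = {}
    for cid, residues in chain_atoms.items():
        out = []
        for seqid, name, atoms in residues:
            atom_objs = {
                an: Atom(an, an[0], np.asarray(xyz, dtype=float), 20.0)
                for an, xyz in atoms.items()}
            out.append(Residue(cid, seqid, name, bool(atom_objs), atom_objs))
        chains[cid] = out
    return StructureModel(chains)


@pytest.fixture
def make_structure():
    return build_model
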