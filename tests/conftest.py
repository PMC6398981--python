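"""Shared fixtures: synthetic bundles, a hand-written PDB, real-data paths."""

from pathlib import Path

import pytest
from hypothesis import settings

from nrampkit import structure_io as sio
from nrampkit import synthetic as syn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

REPO_ROOT = Path(__file__).resolve().parents[1]

#: directory where the deposited coordinate files (6D9W/6C3I/6BU5/6D91 and the
#: ScaNramp/EcoNramp comparators) land when scripts/fetch_data.py is run
STRUCTURE_DIR = REPO_ROOT / "data" / "structures"
#: the family alignment (several MB; fetched separately, never bundled)
ALIGNMENT_PATH = REPO_ROOT / "data" / "alignment" / "nramp_msa.fasta"

# 3 residues, 11 atom records, one HETATM water; fixed-format PDB
THREE_RESIDUE_PDB = """\
HEADER    TEST FIXTURE
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00 10.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00 10.00           C
ATOM      7  C   GLY A   2       5.504   2.696   0.000  1.00 10.00           C
ATOM      8  N   SER A   3       6.191   3.828   0.000  1.00 10.00           N
ATOM      9  CA  SER A   3       7.650   3.837   0.000  1.00 10.00           C
ATOM     10  OG  SER A   3       8.165   5.160   0.000  1.00 10.00           O
HETATM   11  O   HOH A 101       4.000   4.000   4.000  1.00 20.00           O
END
"""
THREE_RESIDUE_ATOM_COUNT = 11  # ATOM/HETATM records above


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def three_residue_model(three_residue_pdb):
    return sio.read_structure(three_residue_pdb)


@pytest.fixture
def bundle():
    """Deterministic 4×20 ideal helical bundle with its segment set."""
    return syn.make_helical_bundle(syn.BundleSpec(n_helices=4, residues_per_helix=20))


@pytest.fixture
def bundle_trace(bundle):
    model, _segments = bundle
    return sio.ca_trace(model)
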