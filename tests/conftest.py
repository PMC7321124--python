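"""Shared fixtures: tiny programmatically generated structures and a small
synthetic benchmark reused across test modules."""

import numpy as np
import pytest

from dockpick.io import PocketStructure
from dockpick.synthetic import SyntheticConfig, make_benchmark

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.300  1.00  0.00           C
END
"""

# ethane with explicit 3D coordinates
TOY_SDF = """\
ethane
  toy

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
$$$$
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "protein.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def toy_sdf(tmp_path):
    path = tmp_path / "ligand.sdf"
    path.write_text(TOY_SDF)
    return path


@pytest.fixture
def single_atom_pocket():
    """One hydrophobic carbon at the origin (also excluded volume)."""
    flags = np.zeros((1, 8), dtype=bool)
    flags[0, 0] = True
    flags[0, 7] = True
    return PocketStructure(
        coords=np.zeros((1, 3)),
        vdw_radii=np.array([1.7]),
        channel_flags=flags,
        center=np.zeros(3),
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """60 complexes, 8 protocols, small pockets: fast but fully structured."""
    return make_benchmark(SyntheticConfig(
        n_complexes=60, n_families=8, pocket_atoms=20, n_protocols=8, seed=11,
    ))


@pytest.fixture(scope="session")
def default_benchmark():
    """A small benchmark with the full 14-protocol registry."""
    return make_benchmark(SyntheticConfig(
        n_complexes=40, n_families=6, pocket_atoms=15, seed=3,
    ))
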