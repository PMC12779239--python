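"""Shared fixtures: hand-built PDB text and small synthetic systems."""

import numpy as np
import pytest

from mdnetics.core import read_structure


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z, element, altloc=" ",
              occupancy=1.00):
    return (f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:<3s} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00          {element:>2s}")


@pytest.fixture
def pdb_atom_line():
    return _pdb_atom


#: ALA-GLY dipeptide, backbone + CB, coordinates in Angstrom
DIPEPTIDE_ATOMS = [
    # serial, name, resname, chain, resseq, x, y, z, element
    (1, "N", "ALA", "A", 1, 0.000, 0.000, 0.000, "N"),
    (2, "CA", "ALA", "A", 1, 1.458, 0.000, 0.000, "C"),
    (3, "C", "ALA", "A", 1, 2.009, 1.420, 0.000, "C"),
    (4, "O", "ALA", "A", 1, 1.251, 2.390, 0.000, "O"),
    (5, "CB", "ALA", "A", 1, 1.988, -0.773, -1.199, "C"),
    (6, "H", "ALA", "A", 1, -0.500, -0.800, 0.300, "H"),
    (7, "N", "GLY", "A", 2, 3.332, 1.536, 0.000, "N"),
    (8, "CA", "GLY", "A", 2, 3.987, 2.835, 0.000, "C"),
    (9, "C", "GLY", "A", 2, 5.504, 2.700, 0.000, "C"),
    (10, "O", "GLY", "A", 2, 6.030, 1.593, 0.000, "O"),
    (11, "H", "GLY", "A", 2, 3.820, 0.700, 0.100, "H"),
]


@pytest.fixture
def dipeptide_pdb(tmp_path):
    lines = [_pdb_atom(*a) for a in DIPEPTIDE_ATOMS] + ["END"]
    path = tmp_path / "dipeptide.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def dipeptide(dipeptide_pdb):
    return read_structure(dipeptide_pdb)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
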