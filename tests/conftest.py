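import textwrap

import numpy as np
import pytest

from voxpocket.synthetic_shapes import ShapeSpec, generate_grid
from voxpocket.voxelization import grid_from_occupancy

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)

TWO_CHAIN_PDB = textwrap.dedent(
    """\
    ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
    ATOM      2  CA  ALA A   1      12.560   6.351  -6.500  1.00  0.00           C
    ATOM      3  C   ALA A   1      13.000   7.500  -5.600  1.00  0.00           C
    TER
    ATOM      4  N   GLY B   2      20.000   5.000  -2.000  1.00  0.00           N
    ATOM      5  CA  GLY B   2      21.400   5.200  -2.100  1.00  0.00           C
    TER
    HETATM    6  C1  LIG A 900      12.000   8.000  -4.000  1.00  0.00           C
    HETATM    7  O   HOH A 901      30.000  30.000  30.000  1.00  0.00           O
    END
    """
)

ATOM_HET_PDB = textwrap.dedent(
    """\
    ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
    HETATM    2  C1  LIG A 900       3.000   0.000   0.000  1.00  0.00           C
    END
    """
)

ALTLOC_PDB = textwrap.dedent(
    """\
    ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C
    ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.50  0.00           C
    ATOM      3  CB  ALA A   1       1.000   1.000   1.000  1.00  0.00           C
    END
    """
)

MULTI_MODEL_PDB = textwrap.dedent(
    """\
    MODEL        1
    ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
    ENDMDL
    MODEL        2
    ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C
    ENDMDL
    END
    """
)


@pytest.fixture
def pdb_file(tmp_path):
    """Factory writing PDB text to a temp file and returning the path."""

    def write(text, name="input.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write


@pytest.fixture(scope="session")
def slab_grid():
    return generate_grid(ShapeSpec("slab", thickness=6.0, extent=30.0))


@pytest.fixture(scope="session")
def cube_grid():
    return generate_grid(ShapeSpec("cube", edge=20.0))


@pytest.fixture(scope="session")
def sphere_grid():
    return generate_grid(ShapeSpec("solid_sphere", radius=8.0))


@pytest.fixture(scope="session")
def well_grid():
    return generate_grid(ShapeSpec("cylindrical_well", well_radius=2.0, well_depth=9.0, extent=30.0))


def cube_occupancy(n, pad):
    """An n^3 solid cube of occupied voxels centred in an (n+2*pad)^3 grid."""
    size = n + 2 * pad
    occ = np.zeros((size, size, size), dtype=bool)
    occ[pad : pad + n, pad : pad + n, pad : pad + n] = True
    return occ


@pytest.fixture
def cube3_grid():
    return grid_from_occupancy(cube_occupancy(3, 2))
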