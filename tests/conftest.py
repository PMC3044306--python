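import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from actsite.structures_io import (Atom, ProteinStructure,
                                   STANDARD_HEAVY_ATOMS)


def full_residue(resname: str, resnum: int, chain: str = "A",
                 offset=(0.0, 0.0, 0.0), rng=None) -> list[Atom]:
    """All heavy atoms of a standard residue at jittered positions."""
    rng = rng or np.random.default_rng(resnum)
    atoms = []
    for i, name in enumerate(STANDARD_HEAVY_ATOMS[resname]):
        xyz = np.asarray(offset, float) + rng.uniform(0, 3, 3) + i * 0.5
        atoms.append(Atom(atom_name=name, residue_name=resname,
                          residue_number=resnum, chain_id=chain,
                          coords=tuple(xyz)))
    return atoms


@pytest.fixture
def three_residue_structure() -> ProteinStructure:
    atoms = (full_residue("SER", 1) + full_residue("HIS", 2, offset=(8, 0, 0))
             + full_residue("ASP", 3, offset=(0, 8, 0)))
    return ProteinStructure(structure_id="fix3res", atoms=atoms)
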