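"""Shared fixtures: toy complexes at several sizes and coarse PB settings.

Everything is generated programmatically; PB-touching fixtures use a
coarsened grid so the suite stays fast while exercising the same code
paths as the production defaults.
"""

import numpy as np
import pytest

from bindscan import synth
from bindscan.core import AtomRecord, MolecularSystem
from bindscan.solvation import PBSettings


@pytest.fixture(scope="session")
def default_fixture():
    """Default 15-residue hairpin complex with ground truth (seed 1)."""
    spec = synth.FixtureSpec(seed=1)
    system, table, truth = synth.build_complex(spec)
    return spec, system, table, truth


@pytest.fixture(scope="session")
def rigid_ensemble(default_fixture):
    """Two identical frames of the default complex (sigma = 0)."""
    spec, system, table, truth = default_fixture
    rigid = synth.FixtureSpec(seed=1, fluctuation_sigma=0.0, n_frames=2)
    return synth.sample_ensemble(system, rigid)


@pytest.fixture(scope="session")
def coarse_pb():
    """Coarse PB grid for fast solvation paths in tests."""
    return PBSettings(grid_spacing=0.9, grid_padding=4.0)


def make_atom(serial, pos, *, name="CA", residue_index=None, residue_name="GLY",
              chain="A", charge=0.0, lj_radius=1.9, lj_epsilon=0.1, mass=12.0):
    return AtomRecord(serial=serial, name=name, element=name[0],
                      residue_index=residue_index or serial,
                      residue_name=residue_name, chain_id=chain,
                      position=np.asarray(pos, float), charge=charge,
                      lj_radius=lj_radius, lj_epsilon=lj_epsilon, mass=mass)


@pytest.fixture
def tiny_complex():
    """4-atom complex (2 receptor + 2 ligand) for cheap PB-involving paths."""
    atoms = [
        make_atom(1, [0.0, 0.0, 0.0], charge=-0.5, chain="R"),
        make_atom(2, [3.0, 0.0, 0.0], charge=0.5, chain="R"),
        make_atom(3, [1.5, 4.0, 0.0], charge=0.3, chain="L"),
        make_atom(4, [1.5, 4.0, 3.0], charge=-0.3, chain="L"),
    ]
    return MolecularSystem(atoms=atoms, bonds=[(1, 2), (3, 4)], role="complex",
                           receptor_serials=frozenset({1, 2}),
                           ligand_serials=frozenset({3, 4}))
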