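"""Shared fixtures: the packaged synthetic reference database and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from c13referee import build_index
from c13referee.chem_core import Bond, Molecule, from_smiles
from c13referee.fixtures import IncrementShiftModel, standard_database

DB_SEED = 1  # the packaged database used throughout the suite


@pytest.fixture(scope="session")
def model():
    return IncrementShiftModel()


@pytest.fixture(scope="session")
def std_db(model):
    return standard_database(seed=DB_SEED, model=model)


@pytest.fixture(scope="session")
def std_index(std_db):
    return build_index(std_db)


@pytest.fixture(scope="session")
def benzene():
    return from_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def toluene():
    return from_smiles("Cc1ccccc1", "toluene")


def permute_molecule(m: Molecule, rng: np.random.Generator) -> Molecule:
    """Random atom relabeling of a molecule (1-based indices)."""
    n = m.n_atoms
    perm = rng.permutation(n)  # new_index0 = perm[old_index0]
    atoms = [None] * n
    for old0, new0 in enumerate(perm):
        a = m.atoms[old0]
        atoms[new0] = type(a)(
            element=a.element, charge=a.charge, implicit_h=a.implicit_h
        )
    bonds = [
        Bond(int(perm[b.a1 - 1]) + 1, int(perm[b.a2 - 1]) + 1,
             order=b.order, aromatic=b.aromatic)
        for b in m.bonds
    ]
    return Molecule(atoms=atoms, bonds=bonds, name=m.name)
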