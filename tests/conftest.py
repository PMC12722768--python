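"""Shared fixtures: converged references, grids, and engines are expensive,
so they are session-scoped and cached."""

from __future__ import annotations

import numpy as np
import pytest

from mpacdens.energy_density import EnergyDensityEngine
from mpacdens.grids import build_grid
from mpacdens.reference import MoleculeSpec, build_reference, one_electron_reference


def _atom(sym, charge=0, basis="desk-dz"):
    return MoleculeSpec(symbols=(sym,), coords=((0.0, 0.0, 0.0),),
                        charge=charge, basis=basis, label=sym)


@pytest.fixture(scope="session")
def he_ref():
    return build_reference(_atom("He"))


@pytest.fixture(scope="session")
def be_ref():
    return build_reference(_atom("Be"))


@pytest.fixture(scope="session")
def ne_ref():
    return build_reference(_atom("Ne"))


@pytest.fixture(scope="session")
def h2_ref():
    return build_reference(
        MoleculeSpec(symbols=("H", "H"), coords=((0, 0, 0), (0, 0, 1.401)),
                     label="H2")
    )


@pytest.fixture(scope="session")
def he_min_ref():
    return build_reference(_atom("He", basis="desk-minimal"))


@pytest.fixture(scope="session")
def h2_min_ref():
    return build_reference(
        MoleculeSpec(symbols=("H", "H"), coords=((0, 0, 0), (0, 0, 1.401)),
                     basis="desk-minimal", label="H2-min")
    )


@pytest.fixture(scope="session")
def h_atom_ref():
    return one_electron_reference(_atom("H"))


@pytest.fixture(scope="session")
def he_engine(he_ref):
    return EnergyDensityEngine(he_ref, build_grid(he_ref.mol, 2))


@pytest.fixture(scope="session")
def be_engine(be_ref):
    return EnergyDensityEngine(be_ref, build_grid(be_ref.mol, 2))


@pytest.fixture(scope="session")
def ne_engine(ne_ref):
    return EnergyDensityEngine(ne_ref, build_grid(ne_ref.mol, 2))


@pytest.fixture(scope="session")
def h2_engine(h2_ref):
    return EnergyDensityEngine(h2_ref, build_grid(h2_ref.mol, 2))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
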