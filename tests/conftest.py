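"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from zernmatch import (
    MatchConfig,
    ToyEnsembleSpec,
    make_hinged_ligand_ensemble,
    make_toy_receptor,
    receptor_pockets,
)
from zernmatch.structures import Structure
from zernmatch.charges import assign_charges_radii


def make_chain(res_numbers, res_name="GLY", atom_names=("N", "CA", "C", "O"), spacing=3.8):
    """Minimal straight-chain structure with the given residue numbers."""
    serial, names, elements, res_names, nums, coords = [], [], [], [], [], []
    s = 1
    for k, rn in enumerate(res_numbers):
        base = np.array([spacing * k, 0.0, 0.0])
        for j, an in enumerate(atom_names):
            serial.append(s)
            names.append(an)
            elements.append(an[0])
            res_names.append(res_name)
            nums.append(rn)
            coords.append(base + np.array([0.4 * j, 0.5 * (j % 2), 0.0]))
            s += 1
    st = Structure(
        serial=np.array(serial),
        name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        res_name=np.array(res_names, dtype=object),
        res_number=np.array(nums, dtype=int),
        chain=np.array(["A"] * len(serial), dtype=object),
        coords=np.array(coords),
    )
    return assign_charges_radii(st)


@pytest.fixture(scope="session")
def toy_receptor():
    return make_toy_receptor(seed=1, n_residues=60)


@pytest.fixture(scope="session")
def toy_pockets(toy_receptor):
    return receptor_pockets(toy_receptor)


@pytest.fixture(scope="session")
def toy_config():
    return MatchConfig.toy_emulation()


@pytest.fixture(scope="session")
def noiseless_ligands():
    spec = ToyEnsembleSpec(
        n_ligand_conformers=5,
        hinge_distance_range=(4.0, 12.0),
        noise_sigma=0.0,
        bend_sigma_deg=0.0,
        ring_tilt_sigma_deg=0.0,
        seed=0,
    )
    return make_hinged_ligand_ensemble(spec)


@pytest.fixture(scope="session")
def numbered_chain():
    """Chain covering residues 100-270, enough to resolve BP3 and BP4."""
    return make_chain(range(100, 271))
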