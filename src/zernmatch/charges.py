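"""Bundled per-atom partial charges and radii.

Real electrostatics pipelines derive per-atom charges with PDB2PQR against a
force field (PARSE, AMBER, CHARMM).  This module instead ships a compact,
deterministic united-atom (implicit hydrogen) charge set for the twenty
standard amino-acid residues, designed so that every residue's heavy-atom
charges sum exactly to its formal charge (0, +1 or -1) under a neutral-termini
convention.  Radii are Bondi-style van der Waals radii per element.

Users who need force-field fidelity should run PDB2PQR themselves and load the
resulting PQR file through :func:`zernmatch.structures.read_structures`; the
explicit charges then take precedence over this table.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CHARGE_TABLE",
    "ELEMENT_RADII",
    "ChargeAssignmentError",
    "assign_charges_radii",
    "element_radius",
    "lookup_charge",
]


class ChargeAssignmentError(KeyError):
    """An atom could not be matched against the bundled charge table."""


#: Bondi-style van der Waals radii in Angstrom, keyed by element symbol.
ELEMENT_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
}

_DEFAULT_RADIUS = 1.70

# Backbone heavy atoms: identical for every residue, charges sum to zero so
# the backbone is neutral and side chains alone carry formal charge.
_BACKBONE: dict[str, float] = {"N": -0.40, "CA": 0.25, "C": 0.60, "O": -0.45}

# Side-chain heavy atoms.  Per-residue sums are exact by construction:
# ASP/GLU -> -1, LYS/ARG -> +1, everything else -> 0.
_SIDE_CHAINS: dict[str, dict[str, float]] = {
    "ALA": {"CB": 0.0},
    "ARG": {
        "CB": 0.0,
        "CG": 0.0,
        "CD": 0.10,
        "NE": -0.25,
        "CZ": 0.80,
        "NH1": 0.175,
        "NH2": 0.175,
    },
    "ASN": {"CB": 0.0, "CG": 0.55, "OD1": -0.55, "ND2": 0.0},
    "ASP": {"CB": 0.0, "CG": 0.10, "OD1": -0.55, "OD2": -0.55},
    "CYS": {"CB": 0.0, "SG": 0.0},
    "GLN": {"CB": 0.0, "CG": 0.0, "CD": 0.55, "OE1": -0.55, "NE2": 0.0},
    "GLU": {"CB": 0.0, "CG": 0.0, "CD": 0.10, "OE1": -0.55, "OE2": -0.55},
    "GLY": {},
    "HIS": {
        "CB": 0.0,
        "CG": 0.10,
        "ND1": -0.30,
        "CD2": 0.10,
        "CE1": 0.40,
        "NE2": -0.30,
    },
    "ILE": {"CB": 0.0, "CG1": 0.0, "CG2": 0.0, "CD1": 0.0},
    "LEU": {"CB": 0.0, "CG": 0.0, "CD1": 0.0, "CD2": 0.0},
    "LYS": {"CB": 0.0, "CG": 0.0, "CD": 0.0, "CE": 0.25, "NZ": 0.75},
    "MET": {"CB": 0.0, "CG": 0.0, "SD": 0.0, "CE": 0.0},
    "PHE": {
        "CB": 0.0,
        "CG": 0.0,
        "CD1": 0.0,
        "CD2": 0.0,
        "CE1": 0.0,
        "CE2": 0.0,
        "CZ": 0.0,
    },
    "PRO": {"CB": 0.0, "CG": 0.0, "CD": 0.0},
    "SER": {"CB": 0.25, "OG": -0.25},
    "THR": {"CB": 0.25, "OG1": -0.25, "CG2": 0.0},
    "TRP": {
        "CB": 0.0,
        "CG": 0.0,
        "CD1": 0.10,
        "CD2": 0.0,
        "NE1": -0.30,
        "CE2": 0.20,
        "CE3": 0.0,
        "CZ2": 0.0,
        "CZ3": 0.0,
        "CH2": 0.0,
    },
    "TYR": {
        "CB": 0.0,
        "CG": 0.0,
        "CD1": 0.0,
        "CD2": 0.0,
        "CE1": 0.0,
        "CE2": 0.0,
        "CZ": 0.25,
        "OH": -0.25,
    },
    "VAL": {"CB": 0.0, "CG1": 0.0, "CG2": 0.0},
}

#: Full (residue, atom) -> charge table, backbone merged into every residue.
CHARGE_TABLE: dict[tuple[str, str], float] = {}
for _res, _side in _SIDE_CHAINS.items():
    for _atom, _q in _BACKBONE.items():
        CHARGE_TABLE[(_res, _atom)] = _q
    # C-terminal carboxylate oxygen; makes the terminal residue -0.45 if
    # present, consistent with treating OXT like the backbone carbonyl O.
    CHARGE_TABLE[(_res, "OXT")] = -0.45
    for _atom, _q in _side.items():
        CHARGE_TABLE[(_res, _atom)] = _q


def element_radius(element: str) -> float:
    """Van der Waals radius in Angstrom for an element symbol."""
    return ELEMENT_RADII.get(element.upper(), _DEFAULT_RADIUS)


def lookup_charge(res_name: str, atom_name: str) -> float:
    """Charge in elementary units for a (residue, atom) pair.

    Raises :class:`ChargeAssignmentError` if the pair is not tabulated.
    """
    key = (res_name.upper(), atom_name.upper())
    try:
        return CHARGE_TABLE[key]
    except KeyError:
        raise ChargeAssignmentError(
            f"no bundled charge for atom {atom_name!r} in residue {res_name!r}; "
            "supply a PQR-like file with explicit charges or enable fallback"
        ) from None


def assign_charges_radii(structure, table=None, *, fallback: bool = False):
    """Populate per-atom partial charges and radii from the bundled table.

    Parameters
    ----------
    structure : zernmatch.structures.Structure
        Structure whose ``charge`` and ``radius`` arrays are (re)assigned.
    table : dict, optional
        Alternative ``(residue, atom) -> charge`` mapping; defaults to
        :data:`CHARGE_TABLE`.
    fallback : bool
        When true, atoms absent from the table get charge 0 instead of
        raising.  Radii always fall back to the element default.

    Returns
    -------
    Structure
        A copy of *structure* with charges and radii filled in.
    """
    if structure.n_atoms == 0:
        raise ValueError("cannot assign charges to an empty structure")
    table = CHARGE_TABLE if table is None else table
    out = structure.copy()
    charges = np.empty(out.n_atoms, dtype=float)
    radii = np.empty(out.n_atoms, dtype=float)
    for i in range(out.n_atoms):
        key = (out.res_name[i].upper(), out.name[i].upper())
        if key in table:
            charges[i] = table[key]
        elif fallback:
            charges[i] = 0.0
        else:
            raise ChargeAssignmentError(
                f"no bundled charge for atom {out.name[i]!r} in residue "
                f"{out.res_name[i]!r} {out.res_number[i]}; enable fallback or "
                "supply explicit charges via a PQR-like file"
            )
        radii[i] = element_radius(out.element[i])
    out.charge = charges
    out.radius = radii
    return out
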