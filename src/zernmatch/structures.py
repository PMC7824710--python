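"""Structure container, PDB/PQR I/O, pocket selections and centroid geometry.

The central in-memory type is :class:`Structure`: a flat, array-backed record
of atoms with coordinates, element, residue identity and per-atom partial
charge and radius.  Multi-model PDB files (here standing in for molecular
dynamics snapshots) map onto :class:`ConformerEnsemble`, a topology-sharing
list of structures.

Binding pockets are residue-number lists (:class:`PocketDefinition`).  Two
named definitions ship with the package: the MKK7 kinase-domain pockets BP3
(N-lobe) and BP4 (inter-lobe cleft), using the kinase's UniProt residue
numbering.  No renumbering is performed; user structures must already match.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .charges import assign_charges_radii, element_radius

__all__ = [
    "BUILTIN_POCKETS",
    "ConformerEnsemble",
    "PocketDefinition",
    "Structure",
    "StructureParseError",
    "aromatic_centroid_distance",
    "read_structures",
    "select_pocket_atoms",
    "side_chain_centroid",
    "write_pdb",
    "write_pqr",
]

#: Backbone heavy-atom names excluded from side-chain centroids.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureParseError(ValueError):
    """A structure file could not be parsed into atoms."""


@dataclass
class Structure:
    """Array-backed molecular structure with per-atom charge and radius.

    All per-atom fields are numpy arrays of equal length; coordinates are in
    Angstrom, charges in elementary-charge units.
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_number: np.ndarray
    chain: np.ndarray
    coords: np.ndarray
    charge: np.ndarray | None = None
    radius: np.ndarray | None = None
    model_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        for attr in ("serial", "name", "element", "res_name", "res_number", "chain"):
            arr = np.asarray(getattr(self, attr))
            if arr.shape[0] != n:
                raise ValueError(f"field {attr} has length {arr.shape[0]}, expected {n}")
            setattr(self, attr, arr)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if self.radius is not None:
            self.radius = np.asarray(self.radius, dtype=float)
            if (self.radius <= 0).any():
                raise ValueError("all atomic radii must be positive")
        if self.charge is not None:
            self.charge = np.asarray(self.charge, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.element])

    def copy(self) -> "Structure":
        return Structure(
            serial=self.serial.copy(),
            name=self.name.copy(),
            element=self.element.copy(),
            res_name=self.res_name.copy(),
            res_number=self.res_number.copy(),
            chain=self.chain.copy(),
            coords=self.coords.copy(),
            charge=None if self.charge is None else self.charge.copy(),
            radius=None if self.radius is None else self.radius.copy(),
            model_index=self.model_index,
            metadata=dict(self.metadata),
        )

    def translated(self, shift) -> "Structure":
        out = self.copy()
        out.coords = out.coords + np.asarray(shift, dtype=float)
        return out

    def subset(self, mask) -> "Structure":
        mask = np.asarray(mask)
        return Structure(
            serial=self.serial[mask],
            name=self.name[mask],
            element=self.element[mask],
            res_name=self.res_name[mask],
            res_number=self.res_number[mask],
            chain=self.chain[mask],
            coords=self.coords[mask],
            charge=None if self.charge is None else self.charge[mask],
            radius=None if self.radius is None else self.radius[mask],
            model_index=self.model_index,
            metadata=dict(self.metadata),
        )

    def residue_numbers(self) -> np.ndarray:
        return np.unique(self.res_number)

    def with_charges(self, **kwargs) -> "Structure":
        """Convenience wrapper around :func:`zernmatch.charges.assign_charges_radii`."""
        return assign_charges_radii(self, **kwargs)


@dataclass
class PocketDefinition:
    """A named binding pocket given as a residue-number list on one chain."""

    name: str
    residue_numbers: tuple[int, ...]
    chain: str = "A"

    def __post_init__(self):
        self.residue_numbers = tuple(int(r) for r in self.residue_numbers)
        if not self.residue_numbers:
            raise ValueError("pocket definition needs at least one residue number")

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "residue_numbers": list(self.residue_numbers),
                "chain": self.chain,
            }
        )


#: MKK7 kinase-domain binding pockets, UniProt numbering.
BUILTIN_POCKETS: dict[str, PocketDefinition] = {
    "BP3": PocketDefinition(
        "BP3", (119, 120, 139, 142, 144, 146, 183, 186, 195)
    ),
    "BP4": PocketDefinition(
        "BP4", (162, 165, 166, 169, 239, 262, 263, 264, 265, 266, 267)
    ),
}


class ConformerEnsemble:
    """Topology-shared list of structures (MD-snapshot stand-in).

    Every member must have the same atom count and atom ordering; per-member
    metadata (frame index, synthetic ground-truth tags) rides along.
    """

    def __init__(self, members, metadata=None):
        members = list(members)
        if not members:
            raise ValueError("ensemble needs at least one member")
        n0 = members[0].n_atoms
        names0 = members[0].name
        for i, m in enumerate(members):
            if m.n_atoms != n0 or not np.array_equal(m.name, names0):
                raise ValueError(f"member {i} breaks shared topology")
        self.members = members
        self.metadata = list(metadata) if metadata is not None else [
            {"frame": i} for i in range(len(members))
        ]
        if len(self.metadata) != len(members):
            raise ValueError("metadata length mismatch")

    def __len__(self):
        return len(self.members)

    def __getitem__(self, i):
        return self.members[i]

    def __iter__(self):
        return iter(self.members)

    @property
    def n_atoms(self) -> int:
        return self.members[0].n_atoms

    def coordinates(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array."""
        return np.stack([m.coords for m in self.members])


# ---------------------------------------------------------------------------
# I/O


def _structure_from_gemmi_model(model, path, model_index):
    serial, name, element, res_name, res_number, chain_ids, xyz = (
        [], [], [], [], [], [], []
    )
    for chain in model:
        for res in chain:
            for atom in res:
                serial.append(atom.serial)
                name.append(atom.name)
                el = atom.element.name if atom.element else ""
                if not el or el == "X":
                    raise StructureParseError(
                        f"{path}: unknown element for atom {atom.name!r} in "
                        f"residue {res.name!r} {res.seqid.num}"
                    )
                element.append(el)
                res_name.append(res.name)
                res_number.append(res.seqid.num)
                chain_ids.append(chain.name)
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not serial:
        raise StructureParseError(f"{path}: model {model_index} contains no atoms")
    return Structure(
        serial=np.array(serial, dtype=int),
        name=np.array(name, dtype=object),
        element=np.array(element, dtype=object),
        res_name=np.array(res_name, dtype=object),
        res_number=np.array(res_number, dtype=int),
        chain=np.array(chain_ids, dtype=object),
        coords=np.array(xyz, dtype=float),
        model_index=model_index,
    )


def _read_pqr_like(path) -> list[Structure]:
    """Parse a PQR-like file: PDB atom fields plus charge and radius columns.

    PDB2PQR output is whitespace-delimited rather than fixed-column, so this
    is a token-based parser; MODEL/ENDMDL records are honoured.
    """
    models: list[Structure] = []
    rows: list[tuple] = []
    model_index = 0

    def flush():
        nonlocal rows, model_index
        if not rows:
            return
        cols = list(zip(*rows))
        models.append(
            Structure(
                serial=np.array(cols[0], dtype=int),
                name=np.array(cols[1], dtype=object),
                element=np.array(cols[2], dtype=object),
                res_name=np.array(cols[3], dtype=object),
                res_number=np.array(cols[4], dtype=int),
                chain=np.array(cols[5], dtype=object),
                coords=np.array(cols[6], dtype=float),
                charge=np.array(cols[7], dtype=float),
                radius=np.array(cols[8], dtype=float),
                model_index=model_index,
            )
        )
        rows = []
        model_index += 1

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("MODEL",):
                flush() if rows else None
            elif rec == "ENDMDL":
                flush()
            elif rec in ("ATOM", "HETATM"):
                tok = line.split()
                try:
                    # ATOM serial name resname [chain] resnum x y z q r
                    if len(tok) == 11:
                        _, ser, nm, rn, ch, rnum, x, y, z, q, r = tok
                    elif len(tok) == 10:
                        _, ser, nm, rn, rnum, x, y, z, q, r = tok
                        ch = "A"
                    else:
                        raise ValueError("unexpected token count")
                    el = "".join(c for c in nm if c.isalpha())[:1].upper()
                    rows.append(
                        (
                            int(ser),
                            nm,
                            el,
                            rn,
                            int(rnum),
                            ch,
                            (float(x), float(y), float(z)),
                            float(q),
                            float(r),
                        )
                    )
                except ValueError as exc:
                    raise StructureParseError(
                        f"{path}:{lineno}: unparseable PQR record ({exc})"
                    ) from None
    flush()
    if not models:
        raise StructureParseError(f"{path}: no atom records found")
    return models


def read_structures(path, format: str = "pdb", *, charge_fallback: bool = False) -> ConformerEnsemble:
    """Read a PDB or PQR-like file into a :class:`ConformerEnsemble`.

    Multi-MODEL files yield one ensemble member per model.  For plain PDB
    input, charges and radii are assigned from the bundled table (raising on
    unknown atoms unless ``charge_fallback``); PQR-like input carries explicit
    charges and radii which are kept as read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("pdb", "pqr-like", "pqr"):
        raise ValueError(f"unsupported format {format!r}")
    if format in ("pqr-like", "pqr"):
        members = _read_pqr_like(path)
        return ConformerEnsemble(members)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from None
    members = []
    for i, model in enumerate(st):
        s = _structure_from_gemmi_model(model, path, i)
        members.append(assign_charges_radii(s, fallback=charge_fallback))
    if not members:
        raise StructureParseError(f"{path}: file contains no models")
    return ConformerEnsemble(members)


def _to_gemmi(structures) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "zernmatch"
    for mi, s in enumerate(structures):
        model = gemmi.Model(mi + 1)
        for chain_name in dict.fromkeys(s.chain):
            ch = gemmi.Chain(str(chain_name))
            in_chain = s.chain == chain_name
            for rnum in dict.fromkeys(s.res_number[in_chain]):
                sel = in_chain & (s.res_number == rnum)
                res = gemmi.Residue()
                res.name = str(s.res_name[np.flatnonzero(sel)[0]])
                res.seqid = gemmi.SeqId(int(rnum), " ")
                res.het_flag = "A"
                for i in np.flatnonzero(sel):
                    a = gemmi.Atom()
                    a.name = str(s.name[i])
                    a.element = gemmi.Element(str(s.element[i]))
                    a.serial = int(s.serial[i])
                    a.pos = gemmi.Position(*s.coords[i])
                    a.occ = 1.0
                    a.b_iso = 0.0
                    res.add_atom(a)
                ch.add_residue(res)
            model.add_chain(ch)
        st.add_model(model)
    return st


def write_pdb(obj, path) -> None:
    """Write a Structure or ConformerEnsemble as (multi-MODEL) PDB."""
    structures = obj.members if isinstance(obj, ConformerEnsemble) else [obj]
    st = _to_gemmi(structures)
    st.write_pdb(str(path))


def write_pqr(obj, path) -> None:
    """Write a whitespace-delimited PQR-like file with charge and radius."""
    structures = obj.members if isinstance(obj, ConformerEnsemble) else [obj]
    multi = len(structures) > 1
    with open(path, "w") as fh:
        for mi, s in enumerate(structures):
            if s.charge is None or s.radius is None:
                raise ValueError("structure lacks charges/radii; assign first")
            if multi:
                fh.write(f"MODEL {mi + 1}\n")
            for i in range(s.n_atoms):
                fh.write(
                    f"ATOM {int(s.serial[i]):6d} {s.name[i]:<4s} {s.res_name[i]:<4s} "
                    f"{s.chain[i]:<2s} {int(s.res_number[i]):5d} "
                    f"{s.coords[i, 0]:10.4f} {s.coords[i, 1]:10.4f} {s.coords[i, 2]:10.4f} "
                    f"{s.charge[i]:9.5f} {s.radius[i]:7.4f}\n"
                )
            if multi:
                fh.write("ENDMDL\n")


# ---------------------------------------------------------------------------
# Selections and centroid geometry


def select_pocket_atoms(structure: Structure, pocket: PocketDefinition) -> Structure:
    """All atoms of the pocket's listed residues, as a Structure subset.

    Residue numbers that do not resolve are reported as warnings; if none
    resolve at all this is an error.  Selection is independent of the order
    of the residue list.
    """
    wanted = set(pocket.residue_numbers)
    present = set(int(r) for r in structure.residue_numbers())
    missing = sorted(wanted - present)
    if len(missing) == len(wanted):
        raise ValueError(
            f"pocket {pocket.name!r}: none of residues {sorted(wanted)} present"
        )
    if missing:
        warnings.warn(
            f"pocket {pocket.name!r}: residues {missing} not found in structure",
            stacklevel=2,
        )
    mask = np.isin(structure.res_number, sorted(wanted))
    if structure.chain is not None and len(set(structure.chain)) > 1:
        mask &= structure.chain == pocket.chain
    return structure.subset(mask)


def side_chain_centroid(structure: Structure, res_number: int) -> np.ndarray:
    """Geometric centre of a residue's side-chain heavy atoms.

    Backbone atoms (N, CA, C, O, OXT) and hydrogens are excluded.
    """
    in_res = structure.res_number == int(res_number)
    if not in_res.any():
        raise ValueError(f"residue {res_number} not present")
    heavy = structure.heavy_mask
    side = in_res & heavy & ~np.isin(structure.name, list(BACKBONE_ATOMS))
    if not side.any():
        raise ValueError(f"residue {res_number} has no side-chain heavy atoms")
    return structure.coords[side].mean(axis=0)


def aromatic_centroid_distance(structure: Structure, res_a: int, res_b: int) -> float:
    """Distance between the side-chain heavy-atom centroids of two residues.

    Used for the aromatic-ring separation of tripeptide conformers, the
    coordinate that distinguishes open from compact conformations.
    """
    ca = side_chain_centroid(structure, res_a)
    cb = side_chain_centroid(structure, res_b)
    return float(np.linalg.norm(ca - cb))
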