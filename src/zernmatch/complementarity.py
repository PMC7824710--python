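"""Shape and electrostatic complementarity between Zernike descriptor sets.

The degree of complementarity between two candidate binding surfaces A and B
is the cosine distance between their descriptor vectors,

    [A-B]shape = D(X_A^shape, X_B^shape),
    [A-B]elec  = ( D(X_A^elec+, X_B^elec-) + D(X_A^elec-, X_B^elec+) ) / 2,

where D(x, y) = 1 - x.y / (|x||y|).  Smaller distance means higher
complementarity.  The electrostatic metric is cross-sign: the positive
sub-surface of one partner should resemble the negative sub-surface of the
other.  Descriptor vectors are non-negative, so both metrics live in [0, 1].

:func:`ensemble_match` runs the all-vs-all matching design between a ligand
conformer ensemble (whole-ligand surfaces) and the pocket patches of a series
of receptor snapshots, producing the long table of per-pair distances that
the ensemble statistics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surface import extract_patch, map_potential, split_by_sign, voxelize_surface
from .zernike import ZernikeDescriptor, descriptor_from_patch

__all__ = [
    "ComplementarityResult",
    "MatchConfig",
    "cosine_distance",
    "elec_complementarity",
    "ensemble_match",
    "results_to_frame",
    "shape_complementarity",
    "structure_descriptors",
]


@dataclass
class ComplementarityResult:
    """Shape/electrostatic distances for one (ligand conformer, snapshot) pair."""

    ligand_id: int
    snapshot_id: int
    pocket: str
    shape_distance: float
    elec_distance: float = np.nan
    elec_defined: bool = False


@dataclass
class MatchConfig:
    """Pipeline settings for the ensemble matching run."""

    order: int = 20
    spacing: float = 0.5
    probe: float = 1.4
    cutoff: float = 6.0
    scale_margin: float = 0.6
    potential_model: str = "coulomb_ddd"
    channels: tuple[str, ...] = ("shape", "elec")

    @classmethod
    def toy_emulation(cls, **overrides) -> "MatchConfig":
        """Configuration for the scaled-down synthetic matching experiments.

        The toy pockets are carved as negative imprints of the bare ligand
        surface, so matching uses probe 0 with a tight patch cutoff that
        keeps the patch to the socket linings; order 10 keeps the many
        replicate runs cheap while retaining the shape contrast.
        """
        base = dict(order=10, probe=0.0, cutoff=3.0, channels=("shape",))
        base.update(overrides)
        return cls(**base)


def cosine_distance(a, b) -> float:
    """1 - cos(a, b); raises on zero vectors (direction undefined)."""
    a = np.asarray(getattr(a, "values", a), dtype=float)
    b = np.asarray(getattr(b, "values", b), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"descriptor length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - np.dot(a, b) / (na * nb))


def shape_complementarity(a: ZernikeDescriptor, b: ZernikeDescriptor) -> float:
    """Cosine distance between two shape-channel descriptor vectors."""
    if a.order != b.order:
        raise ValueError(f"descriptor order mismatch: {a.order} vs {b.order}")
    return cosine_distance(a, b)


def elec_complementarity(a_pos, a_neg, b_pos, b_neg) -> float:
    """Cross-sign electrostatic distance: mean of D(A+, B-) and D(A-, B+).

    Symmetric under swapping the two partners.  Inputs are the elec+ and
    elec- channel descriptors of each partner; any all-zero channel makes the
    result undefined (raise), never silently 0.
    """
    return 0.5 * (cosine_distance(a_pos, b_neg) + cosine_distance(a_neg, b_pos))


def structure_descriptors(structure, pocket=None, config: MatchConfig | None = None):
    """Full per-structure descriptor set: shape and (optionally) elec channels.

    Returns a dict with key ``shape`` and, when the electrostatic channel is
    requested and both sign sub-surfaces are non-empty, keys ``elec+`` and
    ``elec-``.  Missing electrostatic channels are recorded as absent keys.
    """
    config = config or MatchConfig()
    grid = voxelize_surface(structure, spacing=config.spacing, probe=config.probe)
    patch = extract_patch(grid, structure, pocket, cutoff=config.cutoff)
    out = {
        "shape": descriptor_from_patch(
            patch, N=config.order, scale_margin=config.scale_margin
        )
    }
    if "elec" in config.channels:
        mapped = map_potential(patch, structure, model=config.potential_model)
        pos, neg = split_by_sign(mapped)
        for sub in (pos, neg):
            if not sub.is_empty and np.any(sub.function_values() > 0):
                out[sub.label] = descriptor_from_patch(
                    sub, N=config.order, scale_margin=config.scale_margin
                )
    return out


def ensemble_descriptors(ensemble, pocket=None, config: MatchConfig | None = None):
    """Per-member descriptor sets for a whole ensemble (with skip-reporting).

    Returns a list of ``(index, descriptor_dict)``; members on which the
    pocket cannot be resolved (or whose patch is empty) are skipped with a
    warning rather than aborting the run.
    """
    import warnings

    config = config or MatchConfig()
    out = []
    for j, member in enumerate(ensemble):
        try:
            out.append((j, structure_descriptors(member, pocket, config)))
        except ValueError as exc:
            warnings.warn(f"ensemble member {j}: {exc}; skipped")
    return out


def ensemble_match(
    ligand_ensemble,
    pocket_snapshots,
    pocket,
    config: MatchConfig | None = None,
    *,
    ligand_descriptors=None,
    pocket_descriptors=None,
) -> list[ComplementarityResult]:
    """All-vs-all complementarity between ligand conformers and pocket snapshots.

    Each ligand conformer contributes its whole surface; each receptor
    snapshot contributes the surface patch around the pocket residues.  One
    result is produced per (conformer, snapshot) pair; snapshots on which the
    pocket cannot be resolved are skipped with a warning.  Precomputed
    descriptor lists (from :func:`ensemble_descriptors`) can be passed to
    amortize the expensive surface/expansion step across repeated matchings.
    """
    config = config or MatchConfig()
    if ligand_descriptors is None:
        ligand_descriptors = ensemble_descriptors(ligand_ensemble, None, config)
    if pocket_descriptors is None:
        pocket_descriptors = ensemble_descriptors(pocket_snapshots, pocket, config)
    results = []
    for i, ld in ligand_descriptors:
        for j, pdsc in pocket_descriptors:
            shape_d = shape_complementarity(ld["shape"], pdsc["shape"])
            elec_d, defined = np.nan, False
            if all(k in ld for k in ("elec+", "elec-")) and all(
                k in pdsc for k in ("elec+", "elec-")
            ):
                elec_d = elec_complementarity(
                    ld["elec+"], ld["elec-"], pdsc["elec+"], pdsc["elec-"]
                )
                defined = True
            results.append(
                ComplementarityResult(
                    ligand_id=i,
                    snapshot_id=j,
                    pocket=pocket.name if pocket is not None else "whole-ligand",
                    shape_distance=shape_d,
                    elec_distance=elec_d,
                    elec_defined=defined,
                )
            )
    return results


def results_to_frame(results) -> pd.DataFrame:
    """Long-form results table (one row per ligand/snapshot pair)."""
    return pd.DataFrame(
        {
            "ligand_id": [r.ligand_id for r in results],
            "snapshot_id": [r.snapshot_id for r in results],
            "pocket": [r.pocket for r in results],
            "shape_distance": [r.shape_distance for r in results],
            "elec_distance": [r.elec_distance for r in results],
            "elec_defined": [r.elec_defined for r in results],
        }
    )
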