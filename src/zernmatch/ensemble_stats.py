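"""Ensemble-level statistics over complementarity results and trajectories.

This is the statistical layer over the matching pipeline: comparing the
distance distributions of two conformer ensembles (two-sample
Kolmogorov-Smirnov), correlating each conformer's aromatic ring separation
with its shape-complementarity distance (Pearson), and the standard
trajectory stability metrics — backbone RMSD, radius of gyration, per-residue
RMSF and the pocket-volume series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.transform import Rotation

from .structures import ConformerEnsemble, Structure

__all__ = [
    "CorrelationResult",
    "DistributionComparison",
    "backbone_rmsd_series",
    "compare_distributions",
    "correlate_distance_vs_complementarity",
    "pocket_volume_series",
    "radius_of_gyration_series",
    "rmsf_per_residue",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class DistributionComparison:
    """Two-sample KS comparison of two distance distributions."""

    ks_statistic: float
    p_value: float
    n_x: int
    n_y: int
    label_x: str = "x"
    label_y: str = "y"


@dataclass
class CorrelationResult:
    """Pearson correlation of aromatic distance against shape distance."""

    pearson_r: float
    p_value: float
    n_pairs: int
    x_label: str = "aromatic_distance"
    y_label: str = "shape_distance"


def compare_distributions(x, y, label_x: str = "x", label_y: str = "y") -> DistributionComparison:
    """Two-sample Kolmogorov-Smirnov test between two samples.

    The KS statistic is the maximum CDF gap (in [0, 1]); identical samples
    give 0, fully disjoint supports give 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise ValueError("each sample needs at least 5 observations")
    res = sps.ks_2samp(x, y, method="auto")
    return DistributionComparison(
        ks_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_x=int(x.size),
        n_y=int(y.size),
        label_x=label_x,
        label_y=label_y,
    )


def correlate_distance_vs_complementarity(
    results,
    aromatic_distances: dict,
    *,
    aggregate: str = "median",
) -> CorrelationResult:
    """Pearson r between per-conformer aromatic distance and shape distance.

    ``results`` is a list of ComplementarityResult (or an equivalent
    DataFrame); ``aromatic_distances`` maps ligand conformer id to its ring
    centroid separation in Angstrom.  With ``aggregate='median'`` (default)
    each conformer contributes one point: its median shape distance over all
    snapshots.  ``aggregate='none'`` correlates over all pairs instead.

    A negative r means more open conformers are more complementary (smaller
    descriptor distance).
    """
    if aggregate not in ("median", "none"):
        raise ValueError("aggregate must be 'median' or 'none'")
    if isinstance(results, pd.DataFrame):
        frame = results
    else:
        from .complementarity import results_to_frame

        frame = results_to_frame(results)
    missing = set(frame["ligand_id"]) - set(aromatic_distances)
    if missing:
        raise ValueError(f"no aromatic distance for ligand ids {sorted(missing)}")
    if frame["ligand_id"].nunique() < 3:
        raise ValueError("need at least 3 distinct conformers")
    if aggregate == "median":
        per = frame.groupby("ligand_id")["shape_distance"].median()
        x = np.array([aromatic_distances[i] for i in per.index])
        y = per.to_numpy()
    else:
        x = frame["ligand_id"].map(aromatic_distances).to_numpy(dtype=float)
        y = frame["shape_distance"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input on one axis; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(pearson_r=float(r), p_value=float(p), n_pairs=int(x.size))


# ---------------------------------------------------------------------------
# Trajectory metrics


def _superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares superposition (Kabsch); returns transformed coordinates."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return rot.apply(mob_c) + reference.mean(axis=0)


def backbone_rmsd_series(
    ensemble: ConformerEnsemble,
    reference: Structure | None = None,
    *,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame backbone RMSD (Angstrom) to a reference structure.

    Backbone atoms are those named N, CA, C, O.  By default each frame is
    least-squares superposed onto the reference first, so rigid-body motion
    does not register; ``superpose=False`` gives the raw RMSD.
    """
    reference = reference if reference is not None else ensemble[0]
    mask = np.isin(reference.name, BACKBONE_NAMES)
    if not mask.any():
        raise ValueError("no backbone atoms (N, CA, C, O) found")
    ref = reference.coords[mask]
    out = np.empty(len(ensemble))
    for i, frame in enumerate(ensemble):
        mob = frame.coords[mask]
        if superpose:
            mob = _superpose(mob, ref)
        out[i] = np.sqrt(((mob - ref) ** 2).sum(axis=1).mean())
    return out


def radius_of_gyration_series(ensemble: ConformerEnsemble) -> np.ndarray:
    """Per-frame mass-unweighted radius of gyration (Angstrom).

    Rg = sqrt(mean |x_i - x_mean|^2); invariant to rigid rotation and
    translation by construction.
    """
    if ensemble.n_atoms < 2:
        raise ValueError("radius of gyration needs at least 2 atoms")
    coords = ensemble.coordinates()
    centered = coords - coords.mean(axis=1, keepdims=True)
    return np.sqrt((centered**2).sum(axis=2).mean(axis=1))


def rmsf_per_residue(ensemble: ConformerEnsemble, *, superpose: bool = True) -> pd.Series:
    """Per-residue RMSF of heavy-atom centroids about their time means.

    Frames are superposed (all heavy atoms) onto the ensemble mean structure
    before fluctuations are measured, so global drift does not inflate the
    result.  Returns a Series indexed by residue number.
    """
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    first = ensemble[0]
    heavy = first.heavy_mask
    coords = ensemble.coordinates()[:, heavy, :]
    if superpose:
        ref = coords.mean(axis=0)
        for _ in range(2):  # align to mean, update mean, re-align
            coords = np.stack([_superpose(c, ref) for c in coords])
            ref = coords.mean(axis=0)
    res_numbers = first.res_number[heavy]
    series = {}
    for rnum in np.unique(res_numbers):
        sel = res_numbers == rnum
        centroids = coords[:, sel, :].mean(axis=1)  # (n_frames, 3)
        dev = centroids - centroids.mean(axis=0)
        series[int(rnum)] = float(np.sqrt((dev**2).sum(axis=1).mean()))
    return pd.Series(series, name="rmsf")


def pocket_volume_series(ensemble: ConformerEnsemble, pocket, *, spacing: float = 0.8, probe: float = 1.4) -> np.ndarray:
    """Grid-based pocket volume (cubic Angstrom) for every frame."""
    from .surface import pocket_volume, voxelize_surface

    out = np.empty(len(ensemble))
    for i, frame in enumerate(ensemble):
        grid = voxelize_surface(frame, spacing=spacing, probe=probe)
        out[i] = pocket_volume(grid, frame, pocket)
    return out
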