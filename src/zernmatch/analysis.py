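"""Model-style front end: a matching study as a fit/results object pair.

:class:`ComplementarityAnalysis` holds the data of one matching study — one
or more ligand conformer ensembles, a receptor snapshot ensemble and its
pocket definitions — plus the pipeline configuration.  ``fit()`` runs the
all-vs-all matching design for every (ligand ensemble, pocket) combination
and returns a :class:`ComplementarityAnalysisResults` carrying the per-pair
distance table, the ensemble statistics (KS distribution comparisons,
aromatic-distance/shape-distance correlations) and a ``summary()`` text
report; density plots of the distance distributions hang off the results
object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .complementarity import (
    MatchConfig,
    ensemble_descriptors,
    ensemble_match,
    results_to_frame,
)
from .ensemble_stats import (
    compare_distributions,
    correlate_distance_vs_complementarity,
)
from .structures import ConformerEnsemble, PocketDefinition, aromatic_centroid_distance

__all__ = [
    "ComplementarityAnalysis",
    "ComplementarityAnalysisResults",
    "sign_recovery_study",
]


class ComplementarityAnalysis:
    """A shape/electrostatic complementarity matching study.

    Parameters
    ----------
    ligand_ensembles : dict[str, ConformerEnsemble]
        Named conformer ensembles (e.g. ``{"wide": ..., "narrow": ...}``).
    receptor_snapshots : ConformerEnsemble
        Receptor structures (MD-snapshot stand-ins) sharing one topology.
    pockets : dict[str, PocketDefinition]
        Pockets to match against, resolved on every snapshot.
    config : MatchConfig, optional
        Surface/descriptor/matching settings (defaults per module docs).
    aromatic_residues : tuple[int, int]
        Ligand residue numbers whose side-chain centroids define the
        aromatic separation coordinate.
    """

    def __init__(
        self,
        ligand_ensembles: dict[str, ConformerEnsemble],
        receptor_snapshots: ConformerEnsemble,
        pockets: dict[str, PocketDefinition],
        config: MatchConfig | None = None,
        aromatic_residues: tuple[int, int] = (1, 3),
    ):
        if not ligand_ensembles:
            raise ValueError("need at least one ligand ensemble")
        if not pockets:
            raise ValueError("need at least one pocket definition")
        self.ligand_ensembles = dict(ligand_ensembles)
        self.receptor_snapshots = receptor_snapshots
        self.pockets = dict(pockets)
        self.config = config or MatchConfig()
        self.aromatic_residues = tuple(aromatic_residues)

    @classmethod
    def from_synthetic(
        cls,
        seed: int,
        *,
        n_conformers: int = 20,
        n_snapshots: int = 50,
        n_residues: int = 140,
        config: MatchConfig | None = None,
    ) -> "ComplementarityAnalysis":
        """Complete synthetic study: toy receptor + wide/narrow ligand ensembles.

        Convenience constructor for the closed-loop emulation; all randomness
        derives from *seed*.
        """
        from .synthetic import (
            ensemble_spec_preset,
            make_hinged_ligand_ensemble,
            make_receptor_snapshots,
            make_toy_receptor,
            receptor_pockets,
        )

        receptor = make_toy_receptor(seed=seed, n_residues=n_residues)
        snapshots = make_receptor_snapshots(
            receptor, n_snapshots=n_snapshots, seed=seed + 1
        )
        ensembles = {
            preset: make_hinged_ligand_ensemble(
                ensemble_spec_preset(
                    preset, n_ligand_conformers=n_conformers, seed=seed + 2
                )
            )
            for preset in ("wide", "narrow")
        }
        return cls(
            ligand_ensembles=ensembles,
            receptor_snapshots=snapshots,
            pockets=receptor_pockets(receptor),
            config=config or MatchConfig.toy_emulation(),
        )

    def fit(self) -> "ComplementarityAnalysisResults":
        """Run the all-vs-all matching for every (ensemble, pocket) pair."""
        lig_desc = {
            name: ensemble_descriptors(ens, None, self.config)
            for name, ens in self.ligand_ensembles.items()
        }
        frames = []
        for pocket_name, pocket in self.pockets.items():
            pocket_desc = ensemble_descriptors(
                self.receptor_snapshots, pocket, self.config
            )
            for name, ens in self.ligand_ensembles.items():
                res = ensemble_match(
                    ens,
                    self.receptor_snapshots,
                    pocket,
                    self.config,
                    ligand_descriptors=lig_desc[name],
                    pocket_descriptors=pocket_desc,
                )
                frame = results_to_frame(res)
                frame.insert(0, "ligand_set", name)
                frames.append(frame)
        pairs = pd.concat(frames, ignore_index=True)
        aromatic = {
            name: {
                i: aromatic_centroid_distance(member, *self.aromatic_residues)
                for i, member in enumerate(ens)
            }
            for name, ens in self.ligand_ensembles.items()
        }
        return ComplementarityAnalysisResults(
            model=self, pairs=pairs, aromatic_distances=aromatic
        )


@dataclass
class ComplementarityAnalysisResults:
    """Fitted matching study: distance table plus derived statistics."""

    model: ComplementarityAnalysis
    pairs: pd.DataFrame
    aromatic_distances: dict[str, dict[int, float]]
    _corr_cache: dict = field(default_factory=dict, repr=False)

    def distances(self, ligand_set: str, pocket: str, channel: str = "shape") -> np.ndarray:
        """All pairwise distances for one (ligand ensemble, pocket) cell.

        Undefined electrostatic rows are excluded (and counted in the flags),
        never imputed.
        """
        col = {"shape": "shape_distance", "elec": "elec_distance"}[channel]
        sel = self.pairs[
            (self.pairs["ligand_set"] == ligand_set)
            & (self.pairs["pocket"] == pocket)
        ]
        if channel == "elec":
            sel = sel[sel["elec_defined"]]
        return sel[col].to_numpy(dtype=float)

    def ks_test(self, set_x: str, set_y: str, pocket: str, channel: str = "shape"):
        """KS comparison of two ligand ensembles' distance distributions."""
        return compare_distributions(
            self.distances(set_x, pocket, channel),
            self.distances(set_y, pocket, channel),
            label_x=set_x,
            label_y=set_y,
        )

    def correlation(self, ligand_set: str, pocket: str, aggregate: str = "median"):
        """Aromatic-distance vs shape-distance Pearson correlation."""
        key = (ligand_set, pocket, aggregate)
        if key not in self._corr_cache:
            sel = self.pairs[
                (self.pairs["ligand_set"] == ligand_set)
                & (self.pairs["pocket"] == pocket)
            ]
            self._corr_cache[key] = correlate_distance_vs_complementarity(
                sel, self.aromatic_distances[ligand_set], aggregate=aggregate
            )
        return self._corr_cache[key]

    def summary(self) -> str:
        """Plain-text report of distances, KS tests and correlations."""
        lines = []
        lines.append("Surface complementarity matching study")
        lines.append("=" * 54)
        cfg = self.model.config
        lines.append(
            f"order N={cfg.order}  spacing={cfg.spacing} A  probe={cfg.probe} A  "
            f"cutoff={cfg.cutoff} A"
        )
        n_snap = len(self.model.receptor_snapshots)
        sizes = {k: len(v) for k, v in self.model.ligand_ensembles.items()}
        lines.append(f"snapshots: {n_snap}   conformers: {sizes}")
        lines.append("")
        lines.append("median distances by (ligand set, pocket):")
        med = (
            self.pairs.groupby(["ligand_set", "pocket"])[
                ["shape_distance", "elec_distance"]
            ]
            .median()
            .round(4)
        )
        lines.extend("  " + ln for ln in med.to_string().splitlines())
        sets = list(self.model.ligand_ensembles)
        pockets = list(self.model.pockets)
        if len(sets) >= 2:
            lines.append("")
            lines.append("KS tests (shape channel):")
            for pocket in pockets:
                ks = self.ks_test(sets[0], sets[1], pocket)
                lines.append(
                    f"  {sets[0]} vs {sets[1]} @ {pocket}: "
                    f"D={ks.ks_statistic:.3f}  p={ks.p_value:.3g}"
                )
        lines.append("")
        lines.append("aromatic distance vs shape distance (median aggregation):")
        for name in sets:
            for pocket in pockets:
                c = self.correlation(name, pocket)
                lines.append(
                    f"  {name} @ {pocket}: r={c.pearson_r:+.3f}  "
                    f"p={c.p_value:.3g}  n={c.n_pairs}"
                )
        n_undef = int((~self.pairs["elec_defined"]).sum())
        if n_undef:
            lines.append("")
            lines.append(f"pairs with undefined electrostatic distance: {n_undef}")
        return "\n".join(lines)

    def plot_density(self, pocket: str, channel: str = "shape", ax=None, path=None):
        """Kernel-density plot of the distance distributions for one pocket.

        One curve per ligand ensemble (Gaussian KDE, Silverman bandwidth).
        """
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from scipy.stats import gaussian_kde

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for name in self.model.ligand_ensembles:
            d = self.distances(name, pocket, channel)
            if d.size < 2 or np.ptp(d) == 0:
                continue
            kde = gaussian_kde(d, bw_method="silverman")
            grid = np.linspace(d.min() - 0.01, d.max() + 0.01, 256)
            ax.plot(grid, kde(grid), label=name)
        ax.set_xlabel(f"{channel} distance")
        ax.set_ylabel("density")
        ax.set_title(pocket)
        ax.legend()
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        return ax


def sign_recovery_study(
    base_seed: int,
    n_replicates: int = 20,
    *,
    n_conformers: int = 20,
    n_snapshots: int = 50,
    n_residues: int = 140,
    config: MatchConfig | None = None,
) -> pd.DataFrame:
    """Replicated closed-loop emulation of the aromatic-distance correlation.

    For each replicate a fresh toy receptor, snapshot ensemble and wide/narrow
    ligand ensembles are generated and fully matched; the Pearson correlation
    between each conformer's realized ring separation and its median shape
    distance is recorded for every (preset, pocket) cell.  The diagnostic
    cells are wide vs P1 (the open-imprint pocket: opening toward the imprint
    improves complementarity, so r < 0) and narrow vs P2 (the compact-imprint
    pocket, at whose complementarity optimum the narrow band sits, so r is
    noise-dominated).

    Returns a tidy frame with columns replicate, preset, pocket, r, p.
    """
    rows = []
    for rep in range(n_replicates):
        model = ComplementarityAnalysis.from_synthetic(
            seed=base_seed + 101 * rep,
            n_conformers=n_conformers,
            n_snapshots=n_snapshots,
            n_residues=n_residues,
            config=config,
        )
        results = model.fit()
        for preset in model.ligand_ensembles:
            for pocket in model.pockets:
                corr = results.correlation(preset, pocket)
                rows.append(
                    {
                        "replicate": rep,
                        "preset": preset,
                        "pocket": pocket,
                        "r": corr.pearson_r,
                        "p": corr.p_value,
                    }
                )
    return pd.DataFrame(rows)
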