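"""Species x plot community matrix and density standardization.

Subsamples are pooled to the plot before any statistic: the plot is the
analysis unit throughout, and per-subsample resolution survives only in the
specimen records. Abundance entries a[i, p] are raw individual counts;
densities are reported per m^2 of sampled area (five quadrats of 15 x 15 cm
in forests, 20 x 20 cm in grasslands).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import PlotRecord, SpecimenRecord, ValidationError


@dataclass
class CommunityMatrix:
    """Integer abundance matrix with species rows and plot columns.

    ``abundance[i, p]`` is the number of individuals of ``species[i]``
    collected on ``plots[p]`` over all subsamples; ``A_i`` (``total_abundance``)
    sums rows and ``N_i`` (``occupancy``) counts occupied plots.
    """

    species: list[str]
    plots: list[str]
    abundance: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance)
        if self.abundance.shape != (len(self.species), len(self.plots)):
            raise ValidationError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{len(self.species)} species x {len(self.plots)} plots"
            )
        if (self.abundance < 0).any():
            raise ValidationError("abundance entries must be >= 0")

    @property
    def total_abundance(self) -> np.ndarray:
        """A_i: total individuals per species across all plots."""
        return self.abundance.sum(axis=1)

    @property
    def occupancy(self) -> np.ndarray:
        """N_i: number of plots on which each species occurs."""
        return (self.abundance > 0).sum(axis=1)

    def row(self, species: str) -> np.ndarray:
        return self.abundance[self.species.index(species)]

    def subset_plots(self, plot_ids: list[str]) -> "CommunityMatrix":
        idx = [self.plots.index(p) for p in plot_ids]
        return CommunityMatrix(list(self.species), list(plot_ids), self.abundance[:, idx])

    def drop_empty_species(self) -> "CommunityMatrix":
        keep = self.total_abundance > 0
        return CommunityMatrix(
            [s for s, k in zip(self.species, keep) if k],
            list(self.plots),
            self.abundance[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-form (species, plot, abundance) table, zero cells omitted."""
        i, p = np.nonzero(self.abundance)
        return pd.DataFrame(
            {
                "species": [self.species[k] for k in i],
                "plot": [self.plots[k] for k in p],
                "abundance": self.abundance[i, p],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, plots: list[str] | None = None) -> "CommunityMatrix":
        wide = df.pivot_table(
            index="species", columns="plot", values="abundance", aggfunc="sum", fill_value=0
        )
        if plots is not None:
            wide = wide.reindex(columns=plots, fill_value=0)
        return cls(list(wide.index), list(wide.columns), wide.to_numpy(dtype=np.int64))


def build_community_matrix(
    specimens: list[SpecimenRecord], plots: list[PlotRecord]
) -> CommunityMatrix:
    """Tally specimens into a species x plot matrix, pooling subsamples.

    Species that end up with zero total abundance are dropped. Specimens
    whose plot_id is not in ``plots`` are a validation error (all offending
    ids are listed).
    """
    plot_ids = [p.plot_id for p in plots]
    plot_index = {pid: j for j, pid in enumerate(plot_ids)}
    orphans = sorted({s.plot_id for s in specimens if s.plot_id not in plot_index})
    if orphans:
        raise ValidationError(f"specimens reference unknown plot_id(s): {orphans}")
    species = sorted({s.species for s in specimens})
    sp_index = {sp: i for i, sp in enumerate(species)}
    counts = np.zeros((len(species), len(plot_ids)), dtype=np.int64)
    for s in specimens:
        counts[sp_index[s.species], plot_index[s.plot_id]] += 1
    return CommunityMatrix(species, plot_ids, counts).drop_empty_species()


def density_per_m2(matrix: CommunityMatrix, plots: list[PlotRecord]) -> pd.Series:
    """Total individuals per m^2 of sampled area, per plot.

    density[p] = sum_i a[i, p] / (n_subsamples * (side_cm / 100)^2)
    """
    by_id = {p.plot_id: p for p in plots}
    missing = [pid for pid in matrix.plots if pid not in by_id]
    if missing:
        raise ValidationError(f"no plot record for matrix column(s): {missing}")
    areas = np.array([by_id[pid].sampled_area_m2 for pid in matrix.plots])
    if (areas <= 0).any():
        raise ValidationError("zero sampled area on at least one plot")
    totals = matrix.abundance.sum(axis=0)
    return pd.Series(totals / areas, index=matrix.plots, name="density_ind_m2")
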