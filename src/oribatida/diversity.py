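"""Plot-level community descriptors.

Diversity is reported as the effective Shannon diversity e^H — the Hill
number of order 1, i.e. the number of equally common species that would give
the same Shannon entropy. Entropy uses natural logs; e^H is then independent
of the base. Community-weighted mean (CWM) body size averages species' mean
adult lengths weighted by their abundance, so it is invariant to rescaling
counts to densities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .community import CommunityMatrix, density_per_m2
from .records import PlotRecord, SpeciesTrait, ValidationError
from .table1 import Table1


def shannon_entropy(abundances) -> float:
    """Shannon entropy H (nats) of a non-negative abundance vector."""
    a = np.asarray(abundances, dtype=float)
    if a.size == 0 or (a < 0).any():
        raise ValidationError("abundances must be a non-empty, non-negative vector")
    total = a.sum()
    if total <= 0:
        raise ValidationError("Shannon entropy undefined for an all-zero community")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def effective_shannon(abundances) -> float:
    """Effective Shannon diversity e^H (effective number of species)."""
    return float(np.exp(shannon_entropy(abundances)))


def cwm_body_size(
    abundances: dict[str, float] | pd.Series,
    traits: list[SpeciesTrait] | dict[str, SpeciesTrait],
    missing: str = "error",
) -> float:
    """Abundance-weighted mean body size (um) of a community.

    ``missing`` controls species with positive abundance but no body size:
    ``"error"`` (default) raises, ``"drop"`` excludes them with a warning.
    """
    if missing not in ("error", "drop"):
        raise ValueError("missing must be 'error' or 'drop'")
    if not isinstance(traits, dict):
        traits = {t.species: t for t in traits}
    if isinstance(abundances, pd.Series):
        abundances = abundances.to_dict()
    sizes, weights, unsized = [], [], []
    for sp, a in abundances.items():
        if a < 0:
            raise ValidationError(f"negative abundance for {sp!r}")
        if a == 0:
            continue
        t = traits.get(sp)
        if t is None or t.body_size_um is None:
            unsized.append(sp)
            continue
        sizes.append(t.body_size_um)
        weights.append(float(a))
    if unsized:
        if missing == "error":
            raise ValidationError(f"no body size for species with abundance: {unsized}")
        warnings.warn(f"dropping {len(unsized)} species without body size from CWM",
                      stacklevel=2)
    if not weights:
        raise ValidationError("CWM undefined: no individuals with a body size")
    w = np.asarray(weights)
    return float(np.average(sizes, weights=w / w.sum()))


def plot_summaries(
    matrix: CommunityMatrix,
    plots: list[PlotRecord],
    traits: list[SpeciesTrait] | None = None,
    missing_size: str = "error",
) -> pd.DataFrame:
    """Per-plot richness, Shannon H, e^H, density (Ind/m^2) and size CWM.

    Plots with no individuals get NaN diversity/CWM rather than an error.
    CWM columns require ``traits``.
    """
    density = density_per_m2(matrix, plots)
    by_id = {p.plot_id: p for p in plots}
    trait_map = {t.species: t for t in traits} if traits is not None else None
    rows = []
    for j, pid in enumerate(matrix.plots):
        col = matrix.abundance[:, j]
        occupied = col > 0
        rec = {
            "plot_id": pid,
            "region": by_id[pid].region,
            "habitat": by_id[pid].habitat,
            "richness": int(occupied.sum()),
            "density_ind_m2": density[pid],
        }
        if occupied.any():
            rec["shannon_H"] = shannon_entropy(col)
            rec["effective_diversity"] = float(np.exp(rec["shannon_H"]))
            if trait_map is not None:
                rec["cwm_body_size_um"] = cwm_body_size(
                    {sp: int(a) for sp, a in zip(matrix.species, col) if a > 0},
                    trait_map,
                    missing=missing_size,
                )
        else:
            rec["shannon_H"] = np.nan
            rec["effective_diversity"] = np.nan
            if trait_map is not None:
                rec["cwm_body_size_um"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def habitat_shares(
    source: CommunityMatrix | Table1,
    plots: list[PlotRecord] | None = None,
    by_mode: bool = False,
    traits: list[SpeciesTrait] | None = None,
) -> pd.DataFrame:
    """Percentage of individuals (and taxa) per region x habitat.

    For a community matrix, counts are tallied through the plot records.
    For the packaged species table, habitat abundances are estimated as
    total x %occurrence / 100. Without mode resolution the printed suborder
    summary rows are used — they reconcile exactly with the printed regional
    totals, which the species rows do not; with ``by_mode=True`` species
    rows are used, since only they carry a reproductive mode.

    Returns one row per region with forest/grassland percentages of
    individuals summing to 100 (and, with ``by_mode``, per region x habitat
    with mode percentages summing to 100).
    """
    if isinstance(source, Table1):
        return _habitat_shares_fixture(source, by_mode)
    if plots is None:
        raise ValidationError("habitat_shares on a matrix requires plot records")
    by_id = {p.plot_id: p for p in plots}
    long = source.to_frame()
    long["region"] = [by_id[p].region for p in long["plot"]]
    long["habitat"] = [by_id[p].habitat for p in long["plot"]]
    if by_mode:
        if traits is None:
            raise ValidationError("by_mode requires traits")
        mode_map = {t.species: t.mode for t in traits}
        long["mode"] = [mode_map.get(sp, "unknown") for sp in long["species"]]
        tab = long.groupby(["region", "habitat", "mode"])["abundance"].sum().reset_index()
        tab["pct_individuals"] = tab.groupby(["region", "habitat"])["abundance"].transform(
            lambda s: 100.0 * s / s.sum()
        )
        return tab
    tab = long.groupby(["region", "habitat"])["abundance"].sum().reset_index()
    tab["pct_individuals"] = tab.groupby("region")["abundance"].transform(
        lambda s: 100.0 * s / s.sum()
    )
    return tab


def _habitat_shares_fixture(fixture: Table1, by_mode: bool) -> pd.DataFrame:
    rows = []
    for region in ("ALB", "SCH"):
        ha = fixture.habitat_abundance(
            region, rows="species" if by_mode else "higher_taxon"
        )
        if by_mode:
            for habitat in ("forest", "grassland"):
                counts = ha.groupby("mode")[habitat].sum()
                for mode, n in counts.items():
                    rows.append(
                        {
                            "region": region,
                            "habitat": habitat,
                            "mode": mode,
                            "abundance": n,
                            "pct_individuals": 100.0 * n / counts.sum(),
                        }
                    )
        else:
            totals = {h: ha[h].sum() for h in ("forest", "grassland")}
            grand = sum(totals.values())
            for habitat, n in totals.items():
                rows.append(
                    {
                        "region": region,
                        "habitat": habitat,
                        "abundance": n,
                        "pct_individuals": 100.0 * n / grand,
                    }
                )
    return pd.DataFrame(rows)
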