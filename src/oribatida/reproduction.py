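"""Sex ratios, reproductive-mode assignment, gravidity and egg counts.

Reproductive mode follows the field's conventional sex-ratio rule: a species
is taken to be sexual if at least 20% of its sexed individuals are male, and
parthenogenetic otherwise. Literature overrides win over the rule — needed
for parthenogenetic species with rare, spanandric (presumed non-functional)
males. Individuals whose sex could not be determined count toward abundance
but never toward sex-ratio or gravidity denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .records import PlotRecord, SpeciesTrait, SpecimenRecord, ValidationError
from .table1 import Table1

#: minimum male fraction among sexed individuals for a species to be called sexual
MALE_FRACTION_SEXUAL = 0.20


def assign_mode(
    n_males: int, n_females: int, override: str | None = None
) -> tuple[str, str]:
    """Reproductive mode from sexed tallies, as (mode, source).

    A literature override wins when present; otherwise the 20%-male rule
    applies. With no sexed individuals and no override the mode is unknown.
    """
    if override is not None:
        return override, "literature"
    sexed = n_males + n_females
    if sexed == 0:
        return "unknown", "sex_ratio_rule"
    mode = "sexual" if n_males / sexed >= MALE_FRACTION_SEXUAL else "parthenogenetic"
    return mode, "sex_ratio_rule"


def assign_modes(
    specimens: list[SpecimenRecord],
    overrides: dict[str, str] | None = None,
) -> list[SpeciesTrait]:
    """Assign a mode to every species, pooling sexed counts over all plots.

    Pooling maximizes the sample behind each ratio; a per-region view of the
    same tallies is available from :func:`sex_tallies`.
    """
    overrides = overrides or {}
    tallies = sex_tallies(specimens)
    traits = []
    for species, t in tallies.iterrows():
        mode, source = assign_mode(
            int(t["males"]), int(t["females"]), overrides.get(species)
        )
        traits.append(SpeciesTrait(species=species, mode=mode, mode_source=source))
    return traits


def sex_tallies(
    specimens: list[SpecimenRecord],
    plots: list[PlotRecord] | None = None,
) -> pd.DataFrame:
    """Per-species counts of females/males/undetermined (x region if plots given)."""
    keys = ["species"]
    region_of = None
    if plots is not None:
        region_of = {p.plot_id: p.region for p in plots}
        keys = ["species", "region"]
    rows = []
    for s in specimens:
        row = {"species": s.species, "sex": s.sex}
        if region_of is not None:
            row["region"] = region_of[s.plot_id]
        rows.append(row)
    df = pd.DataFrame(rows, columns=keys + ["sex"])
    tab = (
        df.groupby(keys)["sex"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["female", "male", "undetermined"], fill_value=0)
        .rename(columns={"female": "females", "male": "males"})
    )
    tab.columns.name = None
    return tab


def sex_ratio(specimens: list[SpecimenRecord]) -> float | None:
    """Percent females among sexed individuals; None if nothing was sexed."""
    females = sum(1 for s in specimens if s.sex == "female")
    males = sum(1 for s in specimens if s.sex == "male")
    if females + males == 0:
        return None
    return 100.0 * females / (females + males)


def gravidity_and_eggs(
    specimens: list[SpecimenRecord],
) -> tuple[float | None, float | None]:
    """(percent gravid among females, mean eggs per gravid female).

    Egg counts are averaged over gravid females only, so the mean is >= 1
    whenever it exists. Both values are None without females; the mean is
    None without gravid females.
    """
    females = [s for s in specimens if s.sex == "female"]
    if not females:
        return None, None
    gravid = [s for s in females if s.gravid]
    pct = 100.0 * len(gravid) / len(females)
    mean_eggs = float(np.mean([s.egg_count for s in gravid])) if gravid else None
    return pct, mean_eggs


def repro_summary(
    specimens: list[SpecimenRecord],
    plots: list[PlotRecord],
    traits: list[SpeciesTrait] | None = None,
    by: tuple[str, ...] = ("region", "habitat"),
    species_mean: bool = False,
) -> pd.DataFrame:
    """Reproductive metrics per group (any subset of region/habitat/mode/species).

    Default percentages are individual-weighted (total females over total
    sexed). ``species_mean=True`` instead averages per-species percentages
    within the group — both conventions are in use for community-level sex
    ratios and they differ when abundances are skewed.
    """
    valid = {"region", "habitat", "mode", "species"}
    if not set(by) <= valid:
        raise ValidationError(f"grouping keys must be a subset of {sorted(valid)}")
    meta = {p.plot_id: p for p in plots}
    mode_map = {t.species: t.mode for t in traits} if traits else {}
    rows = []
    for s in specimens:
        p = meta.get(s.plot_id)
        if p is None:
            raise ValidationError(f"specimen references unknown plot {s.plot_id!r}")
        rows.append(
            {
                "species": s.species,
                "region": p.region,
                "habitat": p.habitat,
                "mode": mode_map.get(s.species, "unknown"),
                "female": s.sex == "female",
                "male": s.sex == "male",
                "gravid": s.gravid,
                "eggs": s.egg_count,
            }
        )
    df = pd.DataFrame(rows)
    inner = list(by) if "species" in by else list(by) + ["species"]

    def _one(g: pd.DataFrame) -> pd.Series:
        females = int(g["female"].sum())
        males = int(g["male"].sum())
        gravid = int(g["gravid"].sum())
        eggs = g.loc[g["gravid"], "eggs"]
        return pd.Series(
            {
                "n_individuals": len(g),
                "females": females,
                "males": males,
                "pct_females": 100.0 * females / (females + males)
                if females + males
                else np.nan,
                "pct_gravid": 100.0 * gravid / females if females else np.nan,
                "mean_eggs_per_gravid_female": eggs.mean() if gravid else np.nan,
            }
        )

    per_species = df.groupby(inner).apply(_one, include_groups=False).reset_index()
    if "species" in by:
        return per_species
    if species_mean:
        agg = per_species.groupby(list(by)).agg(
            n_individuals=("n_individuals", "sum"),
            pct_females=("pct_females", "mean"),
            pct_gravid=("pct_gravid", "mean"),
            mean_eggs_per_gravid_female=("mean_eggs_per_gravid_female", "mean"),
        )
        return agg.reset_index()
    return df.groupby(list(by)).apply(_one, include_groups=False).reset_index()


def mode_shares(
    source: CommunityMatrix | Table1,
    plots: list[PlotRecord] | None = None,
    traits: list[SpeciesTrait] | None = None,
) -> pd.DataFrame:
    """Percent sexual vs. parthenogenetic individuals and taxa per region x habitat.

    Percentages are taken over individuals (or taxa) of known mode, so the
    two modes sum to 100 within a group; unknown-mode counts are reported in
    their own column, outside the percentages.
    """
    if isinstance(source, Table1):
        rows = []
        for region in ("ALB", "SCH"):
            ha = source.habitat_abundance(region, rows="species")
            sp = source.species_rows(region)
            for habitat in ("forest", "grassland"):
                ind = ha.groupby("mode")[habitat].sum()
                occ_col = "occ_forest" if habitat == "forest" else "occ_grassland"
                present = sp[(sp[occ_col] > 0) & (sp["total"] > 0)]
                taxa = present.groupby("mode")["taxon"].count()
                for mode in ("sexual", "parthenogenetic"):
                    rows.append(
                        {
                            "region": region,
                            "habitat": habitat,
                            "mode": mode,
                            "individuals": ind.get(mode, 0.0),
                            "pct_individuals": 100.0 * ind.get(mode, 0.0) / ind.sum(),
                            "n_taxa": int(taxa.get(mode, 0)),
                            "pct_taxa": 100.0 * taxa.get(mode, 0) / taxa.sum(),
                        }
                    )
        return pd.DataFrame(rows)

    if plots is None or traits is None:
        raise ValidationError("mode_shares on a matrix requires plots and traits")
    mode_map = {t.species: t.mode for t in traits}
    by_id = {p.plot_id: p for p in plots}
    long = source.to_frame()
    long["region"] = [by_id[p].region for p in long["plot"]]
    long["habitat"] = [by_id[p].habitat for p in long["plot"]]
    long["mode"] = [mode_map.get(sp, "unknown") for sp in long["species"]]
    rows = []
    for (region, habitat), g in long.groupby(["region", "habitat"]):
        known = g[g["mode"] != "unknown"]
        ind = known.groupby("mode")["abundance"].sum()
        taxa = known.groupby("mode")["species"].nunique()
        unknown_ind = int(g.loc[g["mode"] == "unknown", "abundance"].sum())
        for mode in ("sexual", "parthenogenetic"):
            rows.append(
                {
                    "region": region,
                    "habitat": habitat,
                    "mode": mode,
                    "individuals": int(ind.get(mode, 0)),
                    "pct_individuals": 100.0 * ind.get(mode, 0) / ind.sum()
                    if ind.sum()
                    else np.nan,
                    "n_taxa": int(taxa.get(mode, 0)),
                    "pct_taxa": 100.0 * taxa.get(mode, 0) / taxa.sum()
                    if taxa.sum()
                    else np.nan,
                    "unknown_individuals": unknown_ind,
                }
            )
    return pd.DataFrame(rows)
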