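"""Abundance-weighted niche statistics and the randomization null model.

For species *i* with abundance ``a[i, p]`` on plots with land-use value
``L_p`` and total abundance ``A_i``, the estimated niche optimum is the
abundance-weighted mean

    AWM_i = sum_p L_p * a[i, p] / A_i,

the niche-breadth proxy is the abundance-weighted standard deviation

    AWSD_i = sqrt( sum_p (a[i, p] / A_i) * (L_p - AWM_i)^2 ),

and CV = AWSD / AWM corrects the breadth for the growth of the standard
deviation with the mean. Both are weighted moments: they do not depend on
total abundance or plot number per se, so rare species stay in the analysis.

The null model asks where a species of the same occupancy and abundance
structure would sit on the gradient if it were placed at random: each
iteration draws the species' N_i occupied plots uniformly without
replacement from the eligible plot set (the plots of the focal habitat in
the region(s) where the species was recorded) and permutes the observed
non-zero abundances onto them. Empirical tail probabilities of the observed
AWM against this distribution give one-sided p-values; at alpha = 0.05 per
tail a species is a

* **winner** if its AWM exceeds the upper 5% tail (tied to high land use),
* **loser** if its AWM falls below the lower 5% tail,
* otherwise **specialized** if its observed CV is narrower than the
  null-expected CV and it occurs on more than one site (CV != 0),
* otherwise an **opportunist**.

No multiple-testing correction is applied across species or parameters;
interpret the per-species labels accordingly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .records import PlotRecord, SpeciesTrait, ValidationError

LABELS = ("winner", "loser", "specialized", "opportunist", "unclassifiable")


def awm(abundances, gradient) -> float:
    """Abundance-weighted mean of the gradient (the niche optimum)."""
    a = np.asarray(abundances, dtype=float)
    L = np.asarray(gradient, dtype=float)
    if a.shape != L.shape:
        raise ValidationError("abundances and gradient must be index-aligned")
    if (a < 0).any():
        raise ValidationError("abundances must be >= 0")
    total = a.sum()
    if total <= 0:
        raise ValidationError("AWM undefined for a species with zero total abundance")
    return float((L * a).sum() / total)


def awsd(abundances, gradient) -> float:
    """Abundance-weighted standard deviation of the gradient (niche breadth)."""
    a = np.asarray(abundances, dtype=float)
    L = np.asarray(gradient, dtype=float)
    m = awm(a, L)
    w = a / a.sum()
    return float(np.sqrt((w * (L - m) ** 2).sum()))


@dataclass(frozen=True)
class NicheEstimate:
    """Observed AWM/AWSD/CV of one species on one land-use gradient."""

    species: str
    parameter: str
    awm: float
    awsd: float
    cv: float | None  # None when AWM == 0 (CV undefined)
    n_plots_occupied: int
    total_abundance: float


def estimate_niche(
    abundances, gradient, species: str = "", parameter: str = ""
) -> NicheEstimate:
    a = np.asarray(abundances, dtype=float)
    m = awm(a, gradient)
    s = awsd(a, gradient)
    return NicheEstimate(
        species=species,
        parameter=parameter,
        awm=m,
        awsd=s,
        cv=(s / m) if m != 0 else None,
        n_plots_occupied=int((a > 0).sum()),
        total_abundance=float(a.sum()),
    )


@dataclass
class NullDistribution:
    """Monte-Carlo AWM/AWSD/CV samples for one species and parameter."""

    species: str
    parameter: str
    awm: np.ndarray = field(repr=False)
    awsd: np.ndarray = field(repr=False)
    cv: np.ndarray = field(repr=False)  # NaN where the sampled AWM == 0
    eligible_gradient: np.ndarray = field(repr=False)
    iterations: int = 0
    seed: int | None = None


def null_distribution(
    abundances,
    eligible_gradient,
    iterations: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    equal_weights: bool = False,
) -> NullDistribution:
    """Randomize a species' placement across the eligible plots.

    ``abundances`` is the species' observed abundance vector (zeros allowed
    and ignored) or its non-zero multiset. Each iteration selects N_i
    distinct plots uniformly from the eligible set and assigns the non-zero
    abundances to them in random order. ``equal_weights=True`` is a
    sensitivity variant that ignores the abundance structure and weights the
    chosen plots equally.
    """
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    if a.size == 0:
        raise ValidationError("null model needs at least one occupied plot")
    L = np.asarray(eligible_gradient, dtype=float)
    if not np.isfinite(L).all():
        raise ValidationError("gradient values must be finite")
    n_i, n_plots = a.size, L.size
    if n_i > n_plots:
        raise ValidationError(
            f"species occupies {n_i} plots but only {n_plots} are eligible"
        )
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    if equal_weights:
        w = np.full(n_i, 1.0 / n_i)
    else:
        w = a / a.sum()
    # Uniform ordered sample without replacement: argsort of iid uniforms per
    # row gives a uniformly random permutation; its first N_i entries are the
    # chosen plots in assignment order.
    order = np.argsort(rng.random((iterations, n_plots)), axis=1)[:, :n_i]
    Ls = L[order]
    awm_s = Ls @ w
    awsd_s = np.sqrt(((Ls - awm_s[:, None]) ** 2 * w).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_s = np.where(awm_s != 0, awsd_s / awm_s, np.nan)
    return NullDistribution(
        species="",
        parameter="",
        awm=awm_s,
        awsd=awsd_s,
        cv=cv_s,
        eligible_gradient=L,
        iterations=iterations,
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass(frozen=True)
class SpeciesClassification:
    """Null-model p-values and the winner/loser/specialized/opportunist label."""

    species: str
    parameter: str
    observed_awm: float
    observed_cv: float | None
    p_high: float
    p_low: float
    expected_cv: float
    label: str
    n_plots_occupied: int = 0


def classify(
    estimate: NicheEstimate,
    null: NullDistribution,
    alpha: float = 0.05,
    pseudocount: bool = False,
) -> SpeciesClassification:
    """Label one species from its observed niche and null distribution.

    ``p_high`` is the fraction of null AWMs >= the observed AWM and
    ``p_low`` the fraction <= it; ties count as extreme on both sides, which
    is conservative and symmetric. ``pseudocount=True`` switches to the
    (k + 1) / (n + 1) permutation-test form. The expected CV is the mean of
    the null CVs.
    """
    n = null.awm.size
    if n == 0:
        raise ValidationError("empty null distribution")
    # exact ties between observed and null AWMs are meaningful (discrete
    # placements); a relative tolerance keeps them ties under float noise
    tol = 1e-9 * max(1.0, abs(estimate.awm))
    k_high = int((null.awm >= estimate.awm - tol).sum())
    k_low = int((null.awm <= estimate.awm + tol).sum())
    if pseudocount:
        p_high, p_low = (k_high + 1) / (n + 1), (k_low + 1) / (n + 1)
    else:
        p_high, p_low = k_high / n, k_low / n
    expected_cv = float(np.nanmean(null.cv)) if np.isfinite(null.cv).any() else np.nan
    if estimate.cv is None:
        label = "unclassifiable"
    elif p_high < alpha:
        label = "winner"
    elif p_low < alpha:
        label = "loser"
    elif estimate.cv != 0 and np.isfinite(expected_cv) and estimate.cv < expected_cv:
        label = "specialized"
    else:
        label = "opportunist"
    return SpeciesClassification(
        species=estimate.species,
        parameter=estimate.parameter,
        observed_awm=estimate.awm,
        observed_cv=estimate.cv,
        p_high=p_high,
        p_low=p_low,
        expected_cv=expected_cv,
        label=label,
        n_plots_occupied=estimate.n_plots_occupied,
    )


def _species_seed(master: int, species: str, parameter: str) -> np.random.SeedSequence:
    # Substream per (species, parameter) so adding or removing species never
    # shifts another species' draws.
    digest = hashlib.sha256(f"{species}\x1f{parameter}".encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence([int(master) % 2**31, key])


def classify_all(
    matrix: CommunityMatrix,
    plots: list[PlotRecord],
    parameters: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
    iterations: int = 10_000,
    seed: int = 0,
    equal_weights: bool = False,
) -> pd.DataFrame:
    """Classify every species on every applicable land-use parameter.

    ``parameters`` maps habitat -> parameter names; by default every
    parameter present on any plot of the habitat is used. Species are
    analyzed within each habitat; the null model's eligible set is
    restricted to plots of that habitat in the region(s) where the species
    was recorded anywhere, allowing for distribution boundaries unrelated to
    plot conditions. Rare species (down to a single occupied plot) are kept.
    Deterministic for a given seed.
    """
    by_id = {p.plot_id: p for p in plots}
    missing = [pid for pid in matrix.plots if pid not in by_id]
    if missing:
        raise ValidationError(f"no plot record for matrix column(s): {missing}")
    regions_of_species = _regions_recorded(matrix, by_id)
    results = []
    for habitat in ("forest", "grassland"):
        hab_plots = [p for p in plots if p.habitat == habitat and p.plot_id in by_id]
        hab_ids = [p.plot_id for p in hab_plots if p.plot_id in set(matrix.plots)]
        if not hab_ids:
            continue
        sub = matrix.subset_plots(hab_ids).drop_empty_species()
        sub_cols = {pid: j for j, pid in enumerate(sub.plots)}
        if parameters is not None:
            params = parameters.get(habitat, [])
        else:
            params = sorted({k for p in hab_plots for k in p.landuse})
        for param in params:
            for i, species in enumerate(sub.species):
                eligible_ids = [
                    p.plot_id
                    for p in hab_plots
                    if p.region in regions_of_species[species]
                    and param in p.landuse
                    and p.plot_id in sub_cols
                ]
                L = np.array([by_id[pid].landuse[param] for pid in eligible_ids])
                a = sub.abundance[i][[sub_cols[pid] for pid in eligible_ids]]
                if a.sum() == 0:
                    continue
                est = estimate_niche(a, L, species=species, parameter=param)
                null = null_distribution(
                    a,
                    L,
                    iterations=iterations,
                    seed=_species_seed(seed, species, param),
                    equal_weights=equal_weights,
                )
                cls = classify(est, null, alpha=alpha)
                results.append(
                    {
                        "species": species,
                        "habitat": habitat,
                        "parameter": param,
                        "awm": est.awm,
                        "awsd": est.awsd,
                        "cv": est.cv,
                        "n_plots_occupied": est.n_plots_occupied,
                        "total_abundance": est.total_abundance,
                        "p_high": cls.p_high,
                        "p_low": cls.p_low,
                        "expected_cv": cls.expected_cv,
                        "label": cls.label,
                    }
                )
    return pd.DataFrame(results)


def _regions_recorded(
    matrix: CommunityMatrix, by_id: dict[str, PlotRecord]
) -> dict[str, set[str]]:
    regions: dict[str, set[str]] = {sp: set() for sp in matrix.species}
    for i, sp in enumerate(matrix.species):
        for j, pid in enumerate(matrix.plots):
            if matrix.abundance[i, j] > 0:
                regions[sp].add(by_id[pid].region)
    return regions


def summarize_winners_losers(
    classifications: pd.DataFrame, traits: list[SpeciesTrait]
) -> pd.DataFrame:
    """Percent winner and loser species among sexual vs. parthenogenetic
    species, per habitat x parameter (the study's species-level summary)."""
    mode_map = {t.species: t.mode for t in traits}
    df = classifications.copy()
    df["mode"] = [mode_map.get(sp, "unknown") for sp in df["species"]]
    df = df[df["mode"].isin(["sexual", "parthenogenetic"])]
    rows = []
    for (habitat, param, mode), g in df.groupby(["habitat", "parameter", "mode"]):
        n = len(g)
        rows.append(
            {
                "habitat": habitat,
                "parameter": param,
                "mode": mode,
                "n_species": n,
                "pct_winners": 100.0 * (g["label"] == "winner").mean(),
                "pct_losers": 100.0 * (g["label"] == "loser").mean(),
            }
        )
    return pd.DataFrame(rows)
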