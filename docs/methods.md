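# Methods

## Analysis unit and standardization

The plot is the analysis unit. Specimen records keep subsample resolution
(1–5), but every statistic pools subsamples first: niche statistics,
diversity and regressions are all defined on plot-level abundances. Density
standardization divides a plot's pooled count by its sampled area,
`n_subsamples × (side_cm/100)²` — 0.1125 m² for forests (five 15-cm
quadrats) and 0.2 m² for grasslands (five 20-cm quadrats). All downstream
weighted statistics (e^H, CWM, AWM/AWSD) are scale-invariant in the
abundances, so it is immaterial whether counts or densities feed them; the
package uses counts.

## Diversity and CWM

Shannon entropy H uses natural logs; zeros are ignored; the all-zero vector
is a domain error rather than 0. The reported diversity is e^H, the Hill
number of order 1, which satisfies the replication principle (doubling a
community with a disjoint copy of itself doubles e^H) — this property is
tested directly. CWM body size weights by abundance, not presence. Species
with positive abundance but no recorded size are an error by default; a
drop-with-warning mode exists because trait tables are chronically
incomplete. Body sizes outside 100–1000 µm warn (plausibility band for
adult oribatid mites) but are not rejected.

## Reproductive metrics

The sexuality rule: a species is sexual if at least 20% of its sexed
individuals are male (boundary inclusive), parthenogenetic otherwise;
literature overrides take precedence, which is how spanandric males in
otherwise thelytokous species (e.g. *Tectocepheus*, *Oppiella nova*) are
handled. The default `assign_modes` pools sexed counts across all plots
rather than per region: a species carries a single mode trait, and pooling
maximizes the sample behind each ratio; per-region tallies are available
via `sex_tallies(specimens, plots)` for sensitivity checks.
Undetermined-sex individuals count toward abundance but never toward sex
ratio or gravidity denominators. Gravidity is gravid females / females;
eggs are averaged over gravid females only, hence the mean is ≥ 1 whenever
defined. Group-level percentages are individual-weighted by default
(total females / total sexed); `species_mean=True` averages per-species
percentages instead — the two conventions differ under skewed abundances
and both are in circulation, so both are exposed.

## Niche statistics and the null model

AWM and AWSD are the weighted first and second moments of the gradient
under the species' relative-abundance weights; CV = AWSD/AWM. CV is
undefined when AWM = 0 (possible only if every occupied plot has gradient
value 0); such species are labeled `unclassifiable`. AWSD = 0 exactly when
the species occupies one plot or all its plots share one gradient value.

Null model: each iteration draws N_i distinct plots uniformly from the
eligible set and permutes the species' observed non-zero abundance vector
onto them. Whether abundances should travel with the species is a genuine
design fork; permuting them preserves the abundance structure that the
weighted moments depend on, so it is the default, and an equal-weights
variant (`equal_weights=True`) is exposed for sensitivity analysis. The
eligible set is the focal habitat's plots in the union of regions where the
species has ≥ 1 individual anywhere — regional restriction allows for
distribution boundaries unrelated to plot conditions.

P-values are plain tail proportions: p_high = #(null AWM ≥ observed)/n,
p_low with ≤. Ties count as extreme on both sides (conservative,
symmetric; hence p_high + p_low ≥ 1), and a relative tolerance of 1e-9
keeps genuine discrete ties ties under floating-point noise — without it a
species occupying all plots with equal abundance can be flagged a winner on
rounding error. A (k+1)/(n+1) pseudocount variant is available behind a
flag. The expected CV is the arithmetic mean of the null CVs (not a
percentile); a species is `specialized` only if its observed CV is below
that and nonzero, otherwise `opportunist`. One-sided alpha = 0.05 per tail,
per parameter, with **no multiple-testing correction** across species or
parameters — the classification is descriptive screening, not confirmatory
inference.

Reproducibility: `classify_all` derives one RNG substream per
(species, parameter) from the master seed via a hash, so results are
bit-reproducible and adding or removing species does not shift other
species' draws. Iterations default to 10,000; the calibration tests use
1,000, where the discreteness of the tail proportion (plus tie handling)
makes the realized winner rate sit slightly below the nominal 5%.

## Regression responses

Land-use responses are fit per habitat as plain regressions on plot-level
values: OLS with a two-sided t-test for Gaussian metrics, binomial GLM
(logit) for proportions, Poisson GLM (log) for egg counts, all via
statsmodels. Random plot effects are not used here: once subsamples are
pooled, the plot is the replicate, and mixed models belong to the
habitat/region comparisons that are out of this package's scope. Complete
separation in the binomial fit (all successes or all failures, or an
explosive slope) yields a flagged result with an absent p-value. Egg
counts are modeled untruncated Poisson although gravid females have ≥ 1
egg; the zero-truncation mismatch is mild at the observed means (~2–3
eggs) and is deliberately left as-is to match standard practice, with the
truncation handled correctly in the *generator* instead.

## Synthetic data generator

The generator reproduces the study conditions: 2 regions × 2 habitats ×
15 plots × 5 subsamples = 300 sample units, forest quadrats 15 cm and
grassland 20 cm. Plots span the focal index evenly — forests a management
index on [0, 1] with the three component proportions set equal to it,
grasslands a compound index on [0.5, 3.0] with fertilization/mowing/grazing
scaling with its squared normalized value; the design itself carries no
randomness. Species respond through Gaussian niches,
λ(L) = λ_max · exp(−(L − μ)²/2σ²), with σ = None meaning a flat (neutral)
response; counts are Poisson by default (clean calibration) or negative
binomial (k = 5 default) because real mite counts are overdispersed.
Individuals are spread uniformly over subsamples. Sexual species draw sex
Bernoulli(female fraction 0.59 — the field-typical sexual sex ratio);
parthenogenetic species are all-female up to an optional spanandric-male
rate. Gravidity probabilities default to 0.71 (sexual) and 0.63
(parthenogenetic), egg counts to zero-truncated Poisson with means 2.97
and 1.81 — the reproductive contrasts the field data show.

Presets define the benchmark conditions used by the tests and acceptance
script, chosen once: `null_community` — 500 flat species, λ_max = 20, one
15-plot forest gradient (type-I calibration); `winners_and_losers` — a
100-species pool with 10% planted winners (μ = 1.0) and 10% losers
(μ = 0.0), σ = 0.08, λ_max = 60, against flat neutrals (recovery);
`field_like` — a deterministic 100-taxon pool with 30% parthenogenetic
species, a geometric abundance hierarchy, smaller-bodied forest species,
and a 4× boost of parthenogens in Schorfheide forests to reproduce the
observed mode inversion there. Planted roles are emitted in a separate
truth table that no analysis function accepts — a structural leakage guard.

What the generator does *not* emulate: spatial autocorrelation among plots,
dispersal, temporal dynamics, detection error in sexing, and
within-species body-size variation. Passing calibration/recovery tests
therefore demonstrate the statistical machinery's correctness under the
assumed sampling model, not robustness to those real-data features.

## The packaged species table

The regional species table ships as a CSV fixture (checksummed at load).
Dashes parse to missing, never zero. Species aggregates ("spp.",
family-level rows) are distinct taxa; the italic suborder summaries are
kept as `higher_taxon` rows and excluded from species-level computation.
The source table is internally inconsistent: its ALB mode totals miss the
regional total by 100 individuals, its suborder rows and species rows imply
different habitat splits, and its printed region-level forest shares cannot
all be recovered from its own rows. Region-level individual shares are
therefore computed from the suborder rows (which reconcile exactly with the
regional totals), and mode-resolved shares from the species rows; the
residual disagreements with the printed headline percentages are on the
order of one percentage point and are documented in the tests.

## Problem sizes

Calibration runs use 500 species × 1,000 null iterations and recovery runs
100 species × 1,000 iterations — sizes at which the binomial error of a 5%
rate is well below the effects of interest while the whole suite completes
in seconds.
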