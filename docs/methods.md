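# Methods

This note documents the models, parameter choices and numerical
decisions behind `thermalgarden`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Study design being modelled

Tagged adult colonies from three populations separated by hundreds of
metres (around 30 colonies each) are fragmented and exposed, in three
consecutive years, to a standardized common-garden heat stress: 25 °C
held for 28 days, with daily visual scoring of % tissue necrosis on a 5%
grid. Colonies assayed in at least two of the three years enter the
analysis. The same colonies are genotyped at 14 microsatellite loci, the
site's 15 m-depth daily temperature record provides the summer thermal
context, and a later in-situ survey of the same colonies provides field
necrosis rates.

## Synthetic necrosis panel

The generator draws a latent cumulative propensity per colony × year ×
day,

    L(i, y, d) = mu + beta_year(y) + pi_pop + u_i + s*d + eps(i, y, d),

takes the running maximum over days, and maps it through
`100 * logistic(L)` rounded to the 5% grid. The running maximum
guarantees monotone non-decreasing trajectories from a single latent
path, and grid rounding makes 100% absorbing. The day-by-day onset
dynamics are a stand-in, not a biological claim: the field only reports
endpoint summaries and mean trajectories, so any monotone link
reproducing those is admissible.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| populations × colonies | 3 × 30 | the sampling design |
| years / days | 3 / 28 | the assay design |
| `year_effects` | (0, 0.5, 6.0) | two moderate-impact years (day-28 mean extent ~30–50%) and one lethal year in which virtually all colonies die before day 28 |
| `latent_intercept`, `day_slope` | −4.8, 0.15 | place day-28 necrosis of an average colony in an ordinary year near 35% |
| `sigma_individual` | 0.25 | reproduces the observed structure in which the year factor carries ~90% of the likelihood-based variance partition and individual baselines ~10%, with a clearly significant random intercept |
| `sigma_residual` | 0.5 | day-level scoring and micro-environmental noise; with `sigma_individual` above, fixes the year:individual ratio |
| `sigma_population` | 0 | populations hundreds of metres apart showed no population effect |
| `missing_year_fraction` | 0.13 | completely-at-random single-year dropout, matching the observed retention (about 76 of ~87 colonies complete in all three years) without modelling its cause |

## Fitness PCA

Cases are colony × year, variables daily necrosis. Columns are
standardized (correlation PCA, population-SD scaling, the FactoMineR
convention), an exploratory all-days PCA is reported, and the definitive
PCA uses days ≥ 10 (the early days are nearly constant zeros and carry
no discriminating signal; the trim day is a parameter). Constant columns
are dropped rather than divided by zero. Cases missing any retained day
are dropped (complete-case PCA). PC1 is deterministically oriented to
correlate positively with final-day necrosis, so "high score = high
necrosis" regardless of eigensolver sign conventions; with a fixed SVD
and fixed case sort, scores are reproducible to the bit.

## Box–Cox and response models

λ is chosen by profile maximum likelihood under the fixed
population × year model (the residual structure the transform must
normalise), searched on [−3, 3]. Scores are shifted by `1 − min` only
when non-positive values are present; the shift is recorded in the
output so results are auditable. Shapiro–Wilk and Levene p-values are
reported, not enforced. Note that λ is weakly identified when the
(shifted) scores sit far from zero — all power transforms are then
near-affine — so λ̂ scatters widely on already-normal data while barely
changing the transformed values.

Both response models are fitted by ML (not REML) so log-likelihoods and
AIC are comparable across fixed-effect structures. The statsmodels
MixedLM optimizer can stall in local optima or at the zero-variance
boundary; the package therefore tries several optimizers, keeps the
best-likelihood fit, and never reports a mixed log-likelihood below the
OLS boundary value (a feasible point of the same model). Fits with a
collapsed random-intercept variance are flagged singular rather than
silently accepted. Tukey year contrasts use model-based marginal means
(averaged over populations) with a large-sample studentized-range
reference — an approximation, with no Satterthwaite correction.

## Variance partition

For each factor (year, population, population × year, individual) one
reduced model is fitted on the identical cases: dropping a main factor
also drops its interaction (the hierarchical reading; keeping the full
interaction while dropping a main effect would change nothing under a
full-rank factorial coding), and dropping "individual" removes the
random intercept. The raw contribution is ΔlogLik/Δdf, floored at 0;
percentages renormalise raw contributions to 100 (published analyses of
this kind print values summing to ~101 from rounding; renormalisation
makes the invariant exact).

## Population genetics

- **Weir–Cockerham θ**: multi-allelic variance components a, b, c summed
  over alleles and loci, missing-data aware (per-locus typed counts).
  For identical populations θ is slightly *negative* (s² = 0 with a
  positive finite-sample correction) — expected, not a bug.
  Differentiation p-values permute individuals among populations,
  targeting the same null as the classical Markov-chain exact test but
  desk-scale and dependency-free; p = (1 + b)/(1 + n) is never 0.
- **DAPC**: centred allele-dosage PCA (missing dosages imputed to column
  means, standard practice), k-means with 20 restarts per K, BIC =
  n·log(WSS/n) + K·log(n) on the retained PCs, discriminant analysis for
  the BIC-chosen K. With ~90 individuals, 14 loci and drift-only
  structure at F_ST ≈ 0.03, the between-population variance is far below
  the log(n) penalty, so BIC honestly prefers K = 1–2: crisp K = 3
  recovery needs either stronger differentiation (the tests use
  θ = 0.2) or non-drift structure (linkage, relatedness) that real data
  carry and the Balding–Nichols generator deliberately does not.
- **sMLH**: an individual's heterozygous proportion over its typed loci
  divided by the mean locus heterozygosity over those same loci; mean
  exactly 1 on complete data. Other missing-data standardizations exist
  (e.g. inbreedR's); differences are small and confined to incomplete
  individuals.
- **Heterosis**: OLS slope of nec-int on sMLH against an
  sMLH-permutation null, two-sided Monte-Carlo p.

## Thermal regime

Hobday-style climatology: per day-of-year, observations within ±5 days
across the baseline years are pooled; the pool mean and 90th percentile
are smoothed with a 31-day circular moving average; Feb 29 is
interpolated when its pool is empty. Exceedance runs of the iT90
threshold (strict >, with a 1e-9 °C guard against smoothing round-off)
become MHWs at ≥ 5 days — the common reading of the ≥/> ambiguity in
"more than 5 days", configurable via `min_mhw_duration` — else heat
spikes. Events separated by short gaps are *not* joined by default
(`join_gap = 0`), since short spikes are a distinct object of interest
here. Categories follow the peak fold (T − clim_mean)/(iT90 −
clim_mean): Moderate [1, 2), Strong [2, 3), Severe [3, 4), Extreme ≥ 4.
If a run exceeds a threshold of zero width the fold is undefined and an
explicit error is raised. T23 counts days with *daily mean* ≥ 23 °C
(the series is daily means; a daily-maximum variant would need
sub-daily data). A percentile climatology applied to a noise-free
seasonal cycle flags the annual summit by construction (the windowed
percentile sits below the local maximum); with realistic noise the
threshold width dwarfs this artefact.

## Sensitivity analysis and its null

E_y is the yearly mean PC1 score over the genotypes present in every
year, so every year averages the identical set; per-genotype slopes are
3-point OLS fits against E_y. Averaging cov(P_i, E)/var(E) over the
defining set gives cov(mean_i P_i, E)/var(E) = 1 — the mean slope is
exactly 1, asserted to 1e-10.

The randomization null pairs scores and environmental values at random:
each randomization reassigns the pooled scores to the genotype × year
cells for the regressions, and independently reassigns them to compute
the E_y. This reproduces the two signatures such a null must have — mean
≈ 0, and long tails (roughly ±30 here) because randomized E_y are means
of random scores and can be nearly equal, inflating 3-point slopes.
Recomputing E from the *same* reassignment is not a null at all: the
mean-slope identity pins it at exactly 1. A fixed-E variant
(`refit_env=False`) is provided; it is light-tailed. Because of the
heavy tails, per-slope significance tests would mislead; the package
reports the fraction of observed slopes exceeding the null mean instead.

Sensitivity categories use the null's central 95% interval as the
"slope ≈ 0" band and the first-year median score as the low/high split:
in-band + low → resistant, in-band + high → hypersensitive, above-band →
sensitive, below-band → "other" (flagged). Both thresholds are recorded
in the output so users can re-threshold.

## Problem sizes in the test suite

Simulation-backed checks use sizes chosen to give stable Monte-Carlo
estimates at desk scale: F_ST calibration averages 200 replicate panels
(90 diploids × 14 loci); permutation-null uniformity uses 1,000
replicate datasets with 199 permutations each, KS-compared after mid-p
centring (the (1 + b)/(1 + n) estimator is exact but discrete — its
atoms sit half an atom above a continuous uniform, and a raw KS at this
replicate count can detect that known offset in a perfectly calibrated
test); variance-partition recovery spans 200 panels of 3 × 20 colonies
across year-effect spreads 0–5 (smaller panels leave enough per-panel
Monte-Carlo noise to cap the rank correlation below its asymptote);
trajectory monotonicity is asserted over every draw of property-based
panels.

## What passing tests do and do not show

The generator encodes drift-only genetic structure, completely-at-random
dropout, rectangular thermal anomalies and a single monotone latent
necrosis path. Passing tests therefore demonstrate correctness of the
estimators and their calibration under these mechanisms — they do not
demonstrate robustness to genotyping error, scoring drift between
observers, non-random colony loss, partial tissue recovery (the model is
absorbing), or thermal sensor gaps beyond simple calendar breaks.

## Known limitations

- The mixed-model Tukey contrasts use a large-sample reference; with few
  year levels and small panels the p-values are approximate.
- The variance partition depends on the "drop the factor and its
  interactions" convention; alternative conventions change the small
  population/interaction shares more than the dominant year share.
- GESTE-style Bayesian site-specific F_ST is out of scope; the nearest
  in-scope summary (leave-one-population-out pairwise means) is not that
  statistic and is not labelled as such.
- The DAPC BIC criterion is conservative at weak, drift-only
  differentiation (see above).
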