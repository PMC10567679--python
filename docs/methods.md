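# Methods

This note documents the statistical procedures implemented in `stabdim`,
the assumptions behind them, the synthetic data generator used to test
them, and the numerical and design choices that were genuinely open.

## Climate classification

Each site contributes one growing-season water-balance value per year
(precipitation minus potential evapotranspiration, mm). The series is
z-scored over a long baseline window — by default the full series, which
for the emulated 1901–2021 records is 121 years — giving the SPEI in SD
units. The **sample** standard deviation (n−1) is used; the choice is
configurable (`ddof`) and documented because both conventions appear in
practice and the difference is negligible at baseline lengths above ~30
years.

Seasons are labelled dry when SPEI ≤ −c, wet when SPEI ≥ +c and normal
otherwise. Boundary values count as extreme, consistent with the
percentile phrasing of the cutoffs (dry = at or below the 25th
percentile for c = 0.67 SD; at or below the 10th for c = 1.28 SD). On
standard-normal input the implied class frequencies are Φ(−c) / 1−2Φ(−c)
/ Φ(−c), i.e. roughly 25/50/25% at c = 0.67 — a dry (or wet) season once
every four years — and 10/80/10% at c = 1.28.

An optional detrending mode removes the least-squares linear trend of
SPEI against year before classification, because a monotone trend
concentrates apparent extremes at one end of the record. Residuals are
re-standardized to unit sample sd so the cutoffs stay in SD units.

### Event selection under consecutive extremes

Resistance and recovery presume an isolated pulse perturbation;
consecutive extremes confound them. Two rules, applied to consecutive
season pairs left to right, decide which seasons enter the facet
calculations:

1. For two consecutive extremes of *different* kinds, the former season
   contributes resistance only; the latter contributes neither
   resistance nor recovery.
2. In a run of consecutive extremes of the *same* kind, every season
   contributes resistance (rule 1 permitting), but recovery is computed
   only for a season followed by a qualifying recovery season: a normal
   season or — at the 1.28 SD cutoff only — a same-kind but less extreme
   season. At the 0.67 cutoff this implies only the last season of a run
   can recover.

An extreme in the final experimental year never yields a recovery pair
(the following season is unobserved). Two points were left open by the
verbal form of these rules and are resolved here as package decisions:
resistance is computed for *every* member of a same-kind run, since only
recovery is explicitly restricted; and at the 1.28 cutoff a season whose
same-kind follower is less extreme recovers into that follower even when
it is not the last of its run, which is the direct reading of the
"less extreme recovery season" clause.

## Stability facets

For biomass and richness-like aspects (richness, Hill diversity of order
q ∈ {0, 1, 2}; q = 0 is richness, larger q weights abundant species
more):

* **Invariability** = μ/σ over the experimental years, σ being the
  sample sd (n−1) of residuals from a least-squares fit of value against
  year. The n−1 convention (rather than the regression residual n−2) is
  a documented choice; it cancels in treatment contrasts of
  log-invariability. A perfectly linear series gives infinite
  invariability and is excluded from inference with a warning.
* **Resistance** per selected extreme season: Ȳn/|Ye − Ȳn| with Ȳn the
  arithmetic mean over all normal experimental seasons.
* **Recovery** per selected pair: |Ye − Ȳn|/|Ye+1 − Ȳn|.

For composition, cover vectors on the plot's fixed species axis (zeros
for absences; within a year, the maximum cover per species over repeat
surveys) replace scalar values. Invariability is 1 minus the total
abundance-based multiple-site Bray–Curtis dissimilarity over all
experimental years; whether the total or one of its components
(balanced-variation vs abundance-gradient) is the right summary was an
open question — the total is implemented and the partition is out of
scope. Resistance is the Bray–Curtis *similarity* of the extreme-season
community to the reference community (per-species mean cover over normal
seasons, zeros included), and recovery the after/during similarity
ratio.

Per-event values are averaged within a plot over each kind's selected
events on the natural scale; biomass and richness facet values are then
natural-log transformed to improve variance homogeneity (composition
facets, already similarity-scaled, are not). Mean-then-log rather than
log-then-mean is a documented choice. Zero-deviation events (infinite
resistance), complete recoveries (infinite recovery) and 0/0 recoveries
are excluded from the event means with logged counts: the log scale
requires finite positive values, and a handful of degenerate events
should not erase a plot.

All facets are computed per plot (one plot per treatment × block),
matching the randomized-block design.

## Inference

**Facet responses.** For each aspect × facet, value ~ treatment is fit
by REML with random intercepts for site and for block nested within site
(statsmodels `MixedLM`, a variance component for block within each site
group). The NPK − Control contrast is tested two-tailed against a t
distribution with containment denominator degrees of freedom: treatment
varies within blocks, so df = n_obs − n_blocks − 1 (df = n_obs −
n_sites − 1 in the site-only fallback used when the nested fit is
singular, which is flagged). Per-treatment means carry model-based 95%
t-intervals. On balanced data the REML contrast equals the OLS
difference of treatment means, which the tests assert as an oracle.

**Correlation responses.** Within each (site, treatment), Pearson
correlations are computed across blocks for all C(5,2) = 10 facet pairs
within each aspect and all C(3,2) = 3 aspect pairs per facet. With the
canonical three blocks each r rests on n = 3; records are retained (the
design implies it) and n is carried for sensitivity filtering. Raw r is
the mixed-model response (treatment fixed, site random); a Fisher-z
option transforms before fitting and reports means and intervals back on
the r scale. The "significant correlation" display is a 95% model-based
CI of the per-treatment mean r excluding zero; a t-interval over sites
would be the main alternative, and the model-based interval is the
documented choice. No multiple-testing correction is applied across
pairs, matching per-pair significance reporting conventions for this
design. Pairs with fewer than three finite block values or zero variance
are skipped with a log message.

## Synthetic data generator

The generator emulates the design of a globally replicated
nutrient-addition experiment: by default 55 sites, 3 blocks per site
with one Control and one NPK plot each, per-site experiment durations
drawn uniformly from 4–15 years, and a 121-year climate baseline per
site. Climate is AR(1) with unit marginal variance on the z scale
(default autocorrelation 0.3, a typical weak interannual persistence),
scaled to mm and optionally drifted linearly. Climate draws are retried
(deterministically) until the experimental window holds at least one
extreme and one normal season, mirroring the site-inclusion criteria.

Community structure separates a **core** of always-present species with
lognormal-rank covers (few dominants, many rares) from **marginal**
species with small covers whose nested occupancy (rarest dropped first)
implements richness dynamics. During a season with |SPEI| ≥ 0.67 each
aspect deviates from its baseline by sensitivity × |SPEI|: biomass falls
in dry and rises in wet seasons, richness falls in both, and composition
shifts in both (a fraction of core cover moved from dominant to
subordinate species, total cover conserved). One year after an extreme
the deviation is multiplied by `recovery_rate` and decays geometrically
thereafter. NPK plots apply multiplicative treatment effects to the
baselines (default +25% biomass, −20% richness via never-occurring
marginal species, a 15% baseline composition shift) and may carry
distinct sensitivities.

Noise has two components: multiplicative log-normal *measurement* noise
on biomass and cover (`noise_sd`), and a log-normal plot-level
multiplier on the deviation itself (`deviation_noise_sd`, default twice
`noise_sd`) representing response heterogeneity among plots. The second
component is what makes facet values vary across blocks — the raw
material of the correlation analysis — and, because it multiplies the
deviation, it cancels exactly in expectation from log-resistance
treatment contrasts, keeping the imposed effects interpretable. With
`noise_sd = 0` (and `deviation_noise_sd` unset) the dataset is exactly
its noise-free expectation.

`expected_truth` rebuilds each site's deterministic deviation profile
from (config, seed) and evaluates every facet definition by direct
arithmetic — explicit least-squares residuals, inline Bray–Curtis sums —
sharing only the season classifier and event selector with the pipeline
(both unit-tested separately against hand-worked sequences). The
noise-free pipeline must reproduce these values to ≤1e−9 relative error,
which exercises generation, CSV round-trip, ingestion, classification,
event selection, facet formulas and aggregation end to end. The
idealized single-event closed forms — resistance 1/(s·|SPEI|), recovery
1/recovery_rate — hold exactly only when post-extreme carry-over does
not contaminate the normal-season mean, so they are exposed separately
(`ideal_resistance`, `ideal_recovery`) rather than asserted against
pipeline output.

What the generator does **not** emulate: mechanistic plant-population
dynamics, species-level synchrony, spatial structure within plots,
observation gaps, or any attempt to match real site values. Passing
tests therefore demonstrate correctness of the estimators under the
stated generative assumptions, not fidelity to real grassland dynamics.

## Simulation experiment sizes

Calibration and parameter-recovery checks run 200 replicates each at
8 sites × 3 blocks × 10 years; the imposed-deficit experiment doubles
the NPK richness sensitivity (true log-resistance contrast −ln 2) with a
60-species pool and 40% core fraction so that integer rounding of
richness and the core-floor clamp stay small perturbations relative to
the imposed deviations — with coarse pools or tight floors those
discretization artifacts dominate the contrast and its model-based SE no
longer reflects the replicate-to-replicate spread. The single-run
qualitative scenario uses 20 sites with doubled NPK sensitivity for
richness and composition only. Under the null (equal sensitivities,
neutral treatment effects) the facet t-test rejects at ~5.5% at nominal
5% in 200 replicates.

## Numerical choices and degenerate inputs

* Residual sds within 1e−10 of zero (relative to the value scale) are
  treated as exact linear trends → infinite invariability, flagged.
* Bray–Curtis of two empty communities, reference communities with no
  normal season, and Hill diversity of an empty cover vector are hard
  errors; an all-zero year invalidates multiple-site dissimilarity.
* Degenerate mixed-model fits (zero residual variance) fall back to OLS
  with a warning; zero-SE contrasts report p = 1 for a zero estimate and
  p = 0 otherwise.
* Missing plot-years skip the affected events rather than failing the
  plot; a recovery pair with an unobserved follow-up year is dropped.
* All randomness flows from `numpy` `SeedSequence(seed, spawn_key)`
  streams keyed by site and purpose, so datasets are bit-identical under
  a fixed config and seed and independent across sites.

## Known limitations

* Containment df is a convention; with few sites it can be liberal
  compared with Satterthwaite/Kenward–Roger approximations, which
  statsmodels does not provide for this design.
* The event-selection rules resolve runs of three or more mixed extremes
  by left-to-right pairwise application; other readings are conceivable
  and isolated in `select_events`.
* Correlations on three blocks are individually very noisy; the design
  compensates by pooling many sites in the site-level mixed model, not
  by stabilizing individual coefficients.
* The multiple-site Bray–Curtis uses the total dissimilarity; analyses
  wanting the turnover/nestedness-style partition need a different
  summary.
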