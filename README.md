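# stabdim

Stability facets and their dimensionality in grassland nutrient-addition
experiments.

`stabdim` is a Python library for quantifying how plant communities in
randomized-block field experiments (Control vs NPK fertilization, as in
globally replicated nutrient networks) respond to dry and wet growing
seasons. It computes **five facets of ecological stability** —

* **temporal invariability** `μ/σ`, the mean of a property over the
  experimental years divided by the standard deviation of its detrended
  residuals;
* **resistance** during dry and wet growing seasons,
  `Ȳn / |Ye − Ȳn|`, the inverse proportional deviation from the
  normal-season mean `Ȳn` during an extreme season `Ye`;
* **recovery** after dry and wet growing seasons,
  `|Ye − Ȳn| / |Ye+1 − Ȳn|`, the ratio of the deviation during the
  extreme to the deviation one year later —

for **three community aspects**: aboveground biomass, species richness
(and Hill diversity of any order q), and community composition. For
composition the deviations are Bray–Curtis dissimilarities: invariability
is 1 minus the abundance-based multiple-site Bray–Curtis dissimilarity
over all experimental years, resistance is the similarity of the
extreme-season community to a reference community (per-species mean cover
over normal seasons), and recovery is the after/during similarity ratio.

Growing seasons are classified from the site's standardized growing-season
water balance (SPEI, z-scored over a long baseline such as 1901–2021):
dry at SPEI ≤ −0.67 SD, wet at ≥ +0.67 SD (quartile events; 1.28 SD gives
decile events). Consecutive extremes are handled with explicit selection
rules so that resistance and recovery are not confounded by back-to-back
events.

Treatment effects on each facet are tested with linear mixed models
(treatment fixed; site and block-within-site random), and the
*dimensionality* of stability is assessed from pairwise Pearson
correlations among stability measures across blocks within each site and
treatment, themselves compared between treatments with a site-level mixed
model. A synthetic data generator with closed-form ground truth makes the
entire pipeline testable without field data.

## Worked example

```python
import numpy as np
from stabdim import standardize, classify, select_events

rng = np.random.default_rng(0)
years = np.arange(1991, 2021)
wb = 40.0 + 90.0 * rng.standard_normal(years.size)   # seasonal water balance, mm

spei = standardize(wb, years, site_id="demo")
seasons = classify(spei, cutoff=0.67)
events = select_events(seasons, experimental_years=range(2011, 2021))
print(events.resistance_years)
print(events.recovery_pairs)
```

prints

```
((2012, 'wet'), (2015, 'wet'), (2017, 'dry'), (2018, 'dry'))
((2012, 2013, 'wet'), (2015, 2016, 'wet'), (2018, 2019, 'dry'))
```

— four extreme seasons contribute resistance values, and three of them
are followed by a qualifying season one year later, so they also
contribute recovery; 2017 contributes no recovery pair because 2018 is
itself dry (only the last season of a same-kind run can recover).

The scripts in `examples/` walk through each capability end to end:
season classification (`01`), the facet formulas on a hand-sized plot
(`02`), parameter recovery of pipeline facets against closed forms on
noise-free synthetic data (`03`, agreeing to ~1e-15 relative error), and
the full mixed-model analysis of a 20-site simulated experiment (`04`).
Running `python examples/04_treatment_effects.py` prints the per-facet
treatment effects — significantly negative invariability and resistance
for richness and composition (whose climate sensitivity is doubled under
NPK in that scenario), no effect on biomass facets — and the count of
significant correlation pairs, which stays low under both treatments
(high-dimensional stability).

A thin CLI mirrors the pipeline stages:

```bash
stabdim simulate --out data/ --seed 1
stabdim classify --climate data/climate.csv --cutoff 0.67 --out seasons.csv
stabdim run --cover data/cover.csv --biomass data/biomass.csv \
            --climate data/climate.csv --out results/ --seed 1
```

`stabdim run` writes tidy CSVs (classification, events, facets, deviation
summaries, correlations, effect tables) plus a JSON manifest; robustness
modes are exposed as flags (`--cutoff 1.28`, `--detrend-spei`,
`--min-years 10`).

## Layout

```
src/stabdim/
  climate.py     SPEI standardization, season classification, event selection
  stability.py   the five facets for scalar and compositional aspects
  inference.py   mixed-model treatment effects and correlation tables
  synthetic.py   NutNet-like generator with closed-form expected truth
  io.py          CSV readers/validation, cover preparation, site filtering
  pipeline.py    end-to-end orchestration and output bundle
  cli.py         thin click interface
docs/methods.md  model, assumptions, parameter choices, limitations
examples/        narrative scripts, one per capability
```
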