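"""Classify growing seasons and select resistance/recovery events.

Builds a short synthetic water-balance record, standardizes it into SPEI
(z-scores over the full baseline), labels each season dry/normal/wet at
the 0.67 SD cutoff, and applies the consecutive-extreme selection rules.
"""

import numpy as np

from stabdim import classify, select_events, standardize

rng = np.random.default_rng(0)
years = np.arange(1991, 2021)
water_balance = 40.0 + 90.0 * rng.standard_normal(years.size)  # mm per season

spei = standardize(water_balance, years, site_id="demo")
seasons = classify(spei, cutoff=0.67)
events = select_events(seasons, experimental_years=range(2011, 2021))

print("year  SPEI   label")
for year, z, label in zip(seasons.years[-10:], seasons.spei[-10:], seasons.labels[-10:]):
    print(f"{year}  {z:+.2f}  {label}")

print("\nresistance years:", events.resistance_years)
print("recovery pairs:  ", events.recovery_pairs)
print(
    "\nEach resistance year contributes Yn/|Ye - Yn| for that season; each"
    "\nrecovery pair compares the deviation during the extreme season with"
    "\nthe deviation one year later.  Extremes followed by an opposite-kind"
    "\nextreme, and all but the last of a same-kind run, are excluded."
)
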