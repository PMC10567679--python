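"""Compute the five stability facets for one plot by hand-sized inputs.

A 6-year plot with one dry season (2003) shows how temporal invariability,
resistance and recovery are derived for a scalar property (biomass) and
for community composition (cover vectors via Bray-Curtis similarity).
"""

import numpy as np

from stabdim import (
    CoverSeries,
    PlotTimeSeries,
    SeasonClassification,
    bray_curtis,
    composition_resistance,
    mean_normal,
    recovery_value,
    reference_community,
    resistance_value,
    select_events,
    temporal_invariability,
)

years = np.arange(2001, 2007)
labels = np.array(["normal", "normal", "dry", "normal", "normal", "normal"], dtype=object)
spei = np.array([0.1, -0.3, -1.4, 0.2, 0.4, -0.1])
seasons = SeasonClassification("demo", 0.67, years, labels, spei)
events = select_events(seasons)

biomass = PlotTimeSeries("demo", "B1", "Control", years,
                         np.array([310.0, 290.0, 180.0, 260.0, 305.0, 295.0]))
yn = mean_normal(biomass, seasons)
ye = biomass.value_at(2003)
ye1 = biomass.value_at(2004)
print(f"normal-season mean biomass Yn = {yn:.1f} g/m2")
print(f"invariability (mu/sd of detrended residuals) = {temporal_invariability(biomass):.2f}")
print(f"resistance  Yn/|Ye-Yn|        = {resistance_value(yn, ye):.2f}")
print(f"recovery    |Ye-Yn|/|Ye+1-Yn| = {recovery_value(yn, ye, ye1):.2f}")

cover = CoverSeries(
    "demo", "B1", "Control", years, ("grass", "forb", "legume"),
    np.array([
        [60.0, 25.0, 10.0],
        [55.0, 30.0, 10.0],
        [30.0, 45.0, 5.0],   # dry year: composition shifts
        [50.0, 30.0, 9.0],
        [58.0, 26.0, 11.0],
        [57.0, 27.0, 10.0],
    ]),
)
ref = reference_community(cover, seasons)
sim = composition_resistance(cover.row(2003), ref)
print(f"\nreference community (mean normal-season cover): {np.round(ref, 1)}")
print(f"composition resistance (similarity to reference in 2003) = {sim:.3f}")
print(f"corresponding Bray-Curtis dissimilarity = {bray_curtis(cover.row(2003), ref):.3f}")
print(
    "\nResistance above 1 means the deviation during the extreme was smaller"
    "\nthan the normal level itself; recovery above 1 means the community"
    "\nmoved back toward its normal level the following year."
)
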