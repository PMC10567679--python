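"""Full pipeline: treatment effects and the dimensionality of stability.

Simulates a 20-site experiment in which nutrient addition doubles the
climate sensitivity of species richness and community composition but not
of biomass, then fits the two mixed-model designs: treatment effects on
each facet (site and block-in-site random), and treatment effects on the
pairwise correlations among stability measures (site random).
"""

from stabdim import PipelineConfig, SimulationConfig, run_pipeline

sensitivity = {
    "biomass": {"Control": 0.15, "NPK": 0.15},
    "richness": {"Control": 0.10, "NPK": 0.20},
    "composition": {"Control": 0.10, "NPK": 0.20},
}
config = SimulationConfig(n_sites=20, n_years_experiment=10, noise_sd=0.08, seed=0,
                          n_species_pool=60, core_fraction=0.4, sensitivity=sensitivity)
result = run_pipeline(PipelineConfig(simulate=config, seed=0))

print("season counts:", result.manifest["season_counts"])
print("\ntreatment effects (NPK - Control) per aspect x facet:")
cols = ["aspect", "facet", "estimate", "se", "df", "pvalue"]
print(result.facet_effects[cols].round(3).to_string(index=False))

corr = result.correlation_effects
within = corr[corr["comparison_type"] == "within_aspect"]
sig_c = ((within["ci_control_lo"] > 0) | (within["ci_control_hi"] < 0)).sum()
sig_n = ((within["ci_npk_lo"] > 0) | (within["ci_npk_hi"] < 0)).sum()
print(f"\nwithin-aspect correlation pairs: {len(within)}")
print(f"  significant under Control (95% CI excludes 0): {sig_c}")
print(f"  significant under NPK:                         {sig_n}")
print(
    "\nNegative, significant effects appear for richness and composition"
    "\ninvariability and resistance (their sensitivity was doubled under"
    "\nNPK), while biomass facets are unaffected; mostly non-significant"
    "\ncorrelations among facets indicate high-dimensional stability."
)
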