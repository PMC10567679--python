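import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stabdim.inference import (
    correlation_effects_table,
    correlation_tables,
    lmm_correlation_effect,
    lmm_facet_effect,
    pearson,
)
from stabdim.stability import FACETS


def facet_frame(n_sites=4, n_blocks=3, aspects=("biomass", "richness", "composition"),
                effect=0.0, noise=0.1, seed=0):
    """Balanced facet table with site/block structure and an NPK shift."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        site_eff = rng.normal(0, 0.3)
        for b in range(n_blocks):
            block_eff = rng.normal(0, 0.1)
            for trt in ("Control", "NPK"):
                for aspect in aspects:
                    for facet in FACETS:
                        value = (site_eff + block_eff + (effect if trt == "NPK" else 0.0)
                                 + rng.normal(0, noise))
                        rows.append(dict(site=f"s{s}", block=f"B{b}", treatment=trt,
                                         aspect=aspect, facet=facet, value=value, n_events=1))
    return pd.DataFrame(rows)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson([1.0, 2.0, 3.0], [1.0, 3.0, 2.0]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance_and_sign_flip(self, a, b):
        x = np.array([0.3, 1.7, 0.9, 2.5, 1.1])
        y = np.array([1.0, 0.2, 2.2, 1.4, 0.6])
        r = pearson(x, y)
        assert pearson(a * x + b, y) == pytest.approx(r, abs=1e-9)
        assert pearson(-a * x + b, y) == pytest.approx(-r, abs=1e-9)


class TestCorrelationTables:
    def test_pair_counts(self):
        records = correlation_tables(facet_frame())
        within = records[records["comparison_type"] == "within_aspect"]
        among = records[records["comparison_type"] == "among_aspect"]
        per_cell = within.groupby(["site", "treatment", "measure_a"]).size()
        # 10 facet pairs per aspect: each of the 5 facets appears in 4 pairs
        counts = within.groupby(["site", "treatment"]).size()
        assert (counts == 3 * 10).all()
        assert (among.groupby(["site", "treatment"]).size() == 5 * 3).all()

    def test_insufficient_blocks_skipped(self):
        df = facet_frame(n_sites=2, n_blocks=3)
        df = df[~((df["site"] == "s0") & (df["block"] == "B2"))]  # 2 blocks at s0
        records = correlation_tables(df)
        assert not (records["site"] == "s0").any()
        assert (records["site"] == "s1").any()

    def test_pairs_unordered_unique(self):
        records = correlation_tables(facet_frame(n_sites=2))
        key = records[["site", "treatment", "measure_a", "measure_b"]].apply(tuple, axis=1)
        assert key.is_unique


class TestFacetLMM:
    def test_balanced_estimate_equals_mean_difference(self):
        """With balanced data the REML fixed effect is the OLS mean contrast."""
        df = facet_frame(n_sites=4, effect=0.7, noise=0.05, seed=3)
        sub = df[(df["aspect"] == "biomass") & (df["facet"] == "invariability")]
        expected = (sub.loc[sub["treatment"] == "NPK", "value"].mean()
                    - sub.loc[sub["treatment"] == "Control", "value"].mean())
        eff = lmm_facet_effect(df, "biomass", "invariability")
        assert eff.estimate == pytest.approx(expected, abs=1e-6)
        assert eff.pvalue < 0.01
        assert eff.ci_npk[0] < eff.mean_npk < eff.ci_npk[1]

    def test_duplicating_sites_preserves_estimate(self):
        df = facet_frame(n_sites=3, effect=0.4, seed=4)
        dup = df.copy()
        dup["site"] = dup["site"] + "_copy"
        both = pd.concat([df, dup], ignore_index=True)
        a = lmm_facet_effect(df, "richness", "resistance_dry")
        b = lmm_facet_effect(both, "richness", "resistance_dry")
        assert b.estimate == pytest.approx(a.estimate, abs=1e-5)

    def test_sign_flip(self):
        df = facet_frame(n_sites=4, effect=0.5, seed=5)
        flipped = df.copy()
        flipped["value"] = -flipped["value"]
        a = lmm_facet_effect(df, "biomass", "recovery_wet")
        b = lmm_facet_effect(flipped, "biomass", "recovery_wet")
        assert b.estimate == pytest.approx(-a.estimate, abs=1e-6)

    def test_requires_two_sites_and_both_treatments(self):
        df = facet_frame(n_sites=1)
        with pytest.raises(ValueError):
            lmm_facet_effect(df, "biomass", "invariability")
        df2 = facet_frame(n_sites=3)
        with pytest.raises(ValueError):
            lmm_facet_effect(df2[df2["treatment"] == "NPK"], "biomass", "invariability")

    def test_containment_df(self):
        df = facet_frame(n_sites=4, n_blocks=3)
        eff = lmm_facet_effect(df, "biomass", "invariability")
        # 24 plots, 12 blocks -> df = 24 - 12 - 1
        assert eff.df == 24 - 12 - 1


def correlation_frame(values: dict, comparison="within_aspect",
                      m_a="biomass|invariability", m_b="biomass|resistance_dry"):
    rows = []
    for site, per_trt in values.items():
        for trt, r in per_trt.items():
            rows.append(dict(site=site, treatment=trt, comparison_type=comparison,
                             measure_a=m_a, measure_b=m_b, r=r, n=3))
    return pd.DataFrame(rows)


class TestCorrelationLMM:
    def test_constant_response(self):
        df = correlation_frame({f"s{i}": {"Control": 0.4, "NPK": 0.4} for i in range(5)})
        eff = lmm_correlation_effect(df, "biomass|invariability", "biomass|resistance_dry")
        assert eff.estimate == pytest.approx(0.0, abs=1e-8)
        assert eff.mean_control == pytest.approx(0.4, abs=1e-6)
        assert eff.ci_control[0] <= 0.4 <= eff.ci_control[1]

    def test_sign_flip_of_r(self):
        rng = np.random.default_rng(6)
        vals = {f"s{i}": {"Control": rng.uniform(-0.5, 0.5), "NPK": rng.uniform(-0.5, 0.5)}
                for i in range(6)}
        df = correlation_frame(vals)
        flipped = df.copy()
        flipped["r"] = -flipped["r"]
        a = lmm_correlation_effect(df, "biomass|invariability", "biomass|resistance_dry")
        b = lmm_correlation_effect(flipped, "biomass|invariability", "biomass|resistance_dry")
        assert b.estimate == pytest.approx(-a.estimate, abs=1e-6)
        assert b.mean_npk == pytest.approx(-a.mean_npk, abs=1e-6)

    def test_ci_covers_zero_mean_r(self):
        """Model-based 95% CIs cover a true zero mean r at roughly the nominal rate."""
        rng = np.random.default_rng(7)
        covered = 0
        n_rep = 120
        for _ in range(n_rep):
            vals = {f"s{i}": {"Control": rng.normal(0, 0.3), "NPK": rng.normal(0, 0.3)}
                    for i in range(8)}
            eff = lmm_correlation_effect(correlation_frame(vals),
                                         "biomass|invariability", "biomass|resistance_dry")
            if eff.ci_control[0] <= 0.0 <= eff.ci_control[1]:
                covered += 1
        assert covered / n_rep >= 0.85

    def test_fisher_z_reports_r_scale_means(self):
        df = correlation_frame({f"s{i}": {"Control": 0.6, "NPK": 0.2} for i in range(5)})
        eff = lmm_correlation_effect(df, "biomass|invariability", "biomass|resistance_dry",
                                     fisher_z=True)
        assert eff.mean_control == pytest.approx(0.6, abs=1e-4)
        assert eff.mean_npk == pytest.approx(0.2, abs=1e-4)

    def test_effects_table_has_one_row_per_pair(self):
        records = correlation_tables(facet_frame(n_sites=4, seed=8))
        out = correlation_effects_table(records)
        assert len(out) == len(records.groupby(["comparison_type", "measure_a", "measure_b"]))
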