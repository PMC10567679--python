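import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from stabdim.climate import select_events
from stabdim.stability import (
    CoverSeries,
    PlotTimeSeries,
    bray_curtis,
    composition_invariability,
    composition_recovery,
    composition_resistance,
    compute_facet_table,
    deviation_summary,
    hill_diversity,
    mean_normal,
    multisite_bray,
    recovery_value,
    reference_community,
    resistance_value,
    temporal_invariability,
)


def ts(values, start=2001):
    values = np.asarray(values, dtype=float)
    return PlotTimeSeries("s", "B1", "Control", np.arange(start, start + values.size), values)


def cov_series(matrix, start=2001):
    matrix = np.asarray(matrix, dtype=float)
    species = tuple(f"sp{j}" for j in range(matrix.shape[1]))
    years = np.arange(start, start + matrix.shape[0])
    return CoverSeries("s", "B1", "Control", years, species, matrix)


class TestScalarPrimitives:
    def test_mean_normal(self, classification_factory):
        cls = classification_factory("NDN")
        assert mean_normal(ts([10.0, 5.0, 20.0]), cls) == 15.0
        assert mean_normal(ts([7.0, 1.0, 7.0]), cls) == 7.0

    def test_mean_normal_requires_a_normal_year(self, classification_factory):
        with pytest.raises(ValueError, match="normal"):
            mean_normal(ts([1.0, 2.0, 3.0]), classification_factory("DDW"))

    def test_invariability_hand_example(self):
        # mu = 11.5; residuals (-0.3, 0.9, -0.9, 0.3); sd = sqrt(0.6)
        inv = temporal_invariability(ts([10.0, 12.0, 11.0, 13.0]))
        assert np.isclose(inv, 11.5 / math.sqrt(0.6))
        assert np.isclose(inv, 14.8461, atol=5e-3)

    def test_invariability_perfect_trend_is_infinite(self):
        assert math.isinf(temporal_invariability(ts([1.0, 2.0, 3.0, 4.0])))

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, c):
        base = np.array([10.0, 12.0, 11.0, 13.0, 9.0])
        assert np.isclose(temporal_invariability(ts(base)),
                          temporal_invariability(ts(c * base)))
        assert np.isclose(resistance_value(100.0, 80.0), resistance_value(100 * c, 80 * c))
        assert np.isclose(recovery_value(100.0, 60.0, 80.0),
                          recovery_value(100 * c, 60 * c, 80 * c))

    @pytest.mark.parametrize(
        "yn, ye, expected",
        [(100.0, 50.0, 2.0), (100.0, 80.0, 5.0), (100.0, 100.0, math.inf)],
    )
    def test_resistance_examples(self, yn, ye, expected):
        assert resistance_value(yn, ye) == expected

    @pytest.mark.parametrize(
        "yn, ye, ye1, expected",
        [(100.0, 60.0, 80.0, 2.0), (100.0, 60.0, 60.0, 1.0), (100.0, 60.0, 100.0, math.inf)],
    )
    def test_recovery_examples(self, yn, ye, ye1, expected):
        assert recovery_value(yn, ye, ye1) == expected

    def test_recovery_zero_over_zero_is_nan(self):
        assert math.isnan(recovery_value(100.0, 100.0, 100.0))


class TestBrayCurtis:
    def test_identity_disjoint_and_hand_value(self):
        assert bray_curtis(np.array([3.0, 1.0]), np.array([3.0, 1.0])) == 0.0
        assert bray_curtis(np.array([5.0, 0.0]), np.array([0.0, 2.0])) == 1.0
        assert bray_curtis(np.array([6.0, 2.0]), np.array([2.0, 6.0])) == 0.5

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            x = rng.random(12) * (rng.random(12) < 0.7)
            y = rng.random(12) * (rng.random(12) < 0.7)
            if x.sum() + y.sum() == 0:
                continue
            assert np.isclose(bray_curtis(x, y), scipy_braycurtis(x, y), atol=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        x, y = rng.random(6), rng.random(6)
        assert bray_curtis(x, y) == bray_curtis(y, x)

    def test_empty_pair_errors(self):
        with pytest.raises(ValueError):
            bray_curtis(np.zeros(3), np.zeros(3))

    def test_multisite_reduces_to_pairwise_for_two_years(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            m = rng.random((2, 8)) * (rng.random((2, 8)) < 0.7)
            if (m.sum(axis=1) == 0).any():
                continue
            assert np.isclose(multisite_bray(m), bray_curtis(m[0], m[1]), atol=1e-12)

    def test_multisite_hand_value(self):
        m = np.array([[10.0, 0.0], [0.0, 10.0], [5.0, 5.0]])
        assert np.isclose(multisite_bray(m), 40.0 / 60.0)

    def test_multisite_identical_rows_zero(self):
        m = np.tile([4.0, 1.0, 2.0], (5, 1))
        assert multisite_bray(m) == 0.0


class TestCompositionFacets:
    def test_invariability_bounds_and_hand_value(self):
        const = np.tile([5.0, 3.0], (4, 1))
        assert composition_invariability(cov_series(const)) == 1.0
        disjoint = np.eye(4) * 10
        assert composition_invariability(cov_series(disjoint)) == 0.0
        m = np.array([[10.0, 0.0], [0.0, 10.0], [5.0, 5.0], [5.0, 5.0]])
        # brute-force multiple-site value over the 4 years
        assert np.isclose(composition_invariability(cov_series(m)), 1 - multisite_bray(m))

    def test_reference_community(self, classification_factory):
        cls = classification_factory("NDN")
        cov = cov_series([[4.0, 0.0], [9.0, 9.0], [0.0, 4.0]])
        assert np.allclose(reference_community(cov, cls), [2.0, 2.0])

    def test_reference_requires_normal_year(self, classification_factory):
        with pytest.raises(ValueError):
            reference_community(cov_series([[1.0, 1.0]]), classification_factory("D"))

    def test_resistance_examples(self):
        ref = np.array([2.0, 6.0])
        assert composition_resistance(ref, ref) == 1.0
        assert composition_resistance(np.array([6.0, 2.0]), ref) == 0.5
        assert composition_resistance(np.array([0.0, 0.1]), np.array([5.0, 0.0])) == pytest.approx(0.0)

    def test_recovery_examples(self):
        ref = np.array([4.0, 4.0])
        during = np.array([8.0, 0.0])  # similarity 0.5
        assert composition_recovery(during, ref, ref) == pytest.approx(2.0)
        assert composition_recovery(during, during, ref) == pytest.approx(1.0)
        away = np.array([24.0, 0.0])  # similarity 0.25
        assert composition_recovery(during, away, ref) == pytest.approx(0.5)


class TestHill:
    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 2.0])
    def test_equal_covers(self, q):
        assert np.isclose(hill_diversity(np.full(7, 3.3), q), 7.0)

    def test_hand_values(self):
        cover = np.array([50.0, 30.0, 20.0])
        assert hill_diversity(cover, 0) == 3.0
        assert np.isclose(hill_diversity(cover, 1), 2.7998, atol=1e-3)
        assert np.isclose(hill_diversity(cover, 2), 1 / 0.38, atol=1e-9)

    @pytest.mark.parametrize("q", [0.0, 0.7, 1.0, 1.5, 3.0])
    def test_single_species(self, q):
        assert hill_diversity(np.array([0.0, 12.0, 0.0]), q) == pytest.approx(1.0)

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=15))
    @settings(max_examples=100, deadline=None)
    def test_non_increasing_in_q(self, cover):
        cover = np.asarray(cover)
        qs = [0.0, 0.5, 1.0, 1.5, 2.0]
        vals = [hill_diversity(cover, q) for q in qs]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))
        assert vals[0] == np.count_nonzero(cover)


class TestAggregation:
    def make_inputs(self, classification_factory):
        cls = classification_factory("NDNDN")
        events = select_events(cls)
        # biomass chosen so dry-year resistances are 2 and 4
        series = PlotTimeSeries("s", "B1", "Control", np.arange(2001, 2006),
                                np.array([100.0, 50.0, 100.0, 75.0, 100.0]))
        return cls, events, series

    def test_mean_then_log_for_biomass(self, classification_factory):
        cls, events, series = self.make_inputs(classification_factory)
        table = compute_facet_table({"biomass": [series]}, [], {"s": cls}, {"s": events})
        row = table[(table["facet"] == "resistance_dry")].iloc[0]
        assert np.isclose(row["value"], math.log(3.0))
        assert row["n_events"] == 2

    def test_composition_mean_without_log(self, classification_factory):
        cls = classification_factory("NDNDN")
        events = select_events(cls)
        # dry-year communities at similarity 0.4 and 0.6 to the reference
        ref_row = [5.0, 5.0]
        m = np.array([ref_row, [9.0, 1.0], ref_row, [7.0, 3.0], ref_row])
        cov = cov_series(m)
        table = compute_facet_table({}, [cov], {"s": cls}, {"s": events})
        row = table[table["facet"] == "resistance_dry"].iloc[0]
        sims = [1 - bray_curtis(m[1], np.array(ref_row)), 1 - bray_curtis(m[3], np.array(ref_row))]
        assert np.isclose(row["value"], np.mean(sims))

    def test_single_event_is_identity(self, classification_factory):
        cls = classification_factory("NDN")
        events = select_events(cls)
        series = PlotTimeSeries("s", "B1", "Control", np.arange(2001, 2004),
                                np.array([100.0, 50.0, 100.0]))
        table = compute_facet_table({"biomass": [series]}, [], {"s": cls}, {"s": events})
        row = table[table["facet"] == "resistance_dry"].iloc[0]
        assert np.isclose(row["value"], math.log(2.0))

    def test_infinite_events_are_excluded(self, classification_factory):
        cls = classification_factory("NDNDN")
        events = select_events(cls)
        # first dry year sits exactly at the normal level -> infinite resistance
        series = PlotTimeSeries("s", "B1", "Control", np.arange(2001, 2006),
                                np.array([100.0, 100.0, 100.0, 50.0, 100.0]))
        table = compute_facet_table({"biomass": [series]}, [], {"s": cls}, {"s": events})
        row = table[table["facet"] == "resistance_dry"].iloc[0]
        assert np.isclose(row["value"], math.log(2.0))
        assert row["n_events"] == 1


class TestDeviationSummary:
    def test_hand_values(self, classification_factory):
        cls = classification_factory("NDN")
        events = select_events(cls)
        series = PlotTimeSeries("s", "B1", "Control", np.arange(2001, 2004),
                                np.array([100.0, 80.0, 100.0]))
        out = deviation_summary({"biomass": [series]}, [], {"s": cls}, {"s": events})
        during = out[(out["timing"] == "during")].iloc[0]
        assert during["mean_change"] == -20.0
        assert during["mean_absolute"] == 20.0
        assert during["mean_proportional"] == pytest.approx(-0.2)
        after = out[(out["timing"] == "after")].iloc[0]
        assert after["mean_change"] == 0.0

    def test_symmetric_events_cancel_in_mean_change(self, classification_factory):
        cls = classification_factory("NDNDN")
        events = select_events(cls)
        series = PlotTimeSeries("s", "B1", "Control", np.arange(2001, 2006),
                                np.array([100.0, 80.0, 100.0, 120.0, 100.0]))
        out = deviation_summary({"biomass": [series]}, [], {"s": cls}, {"s": events})
        during = out[out["timing"] == "during"].iloc[0]
        assert during["mean_change"] == 0.0
        assert during["mean_absolute"] == 20.0
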