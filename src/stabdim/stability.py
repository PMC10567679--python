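"""Five stability facets for three plant-community aspects at plot level.

Facets
------
invariability
    Temporal mean divided by the sd of detrended residuals (biomass,
    richness, Hill diversity) or the multiple-site Bray-Curtis similarity
    over all experimental years (composition).
resistance_dry / resistance_wet
    Inverse proportional deviation from the normal-season mean during an
    extreme season, ``Yn_bar / |Ye - Yn_bar|``; for composition, the
    Bray-Curtis similarity of the extreme-season community to the
    normal-season reference community.
recovery_dry / recovery_wet
    ``|Ye - Yn_bar| / |Ye+1 - Yn_bar|``; for composition, the ratio of the
    similarity to the reference one year after the extreme to the
    similarity during it.

Per-event values are averaged within a plot over the selected events of
each kind, and biomass/richness facets are natural-log transformed for
inference.  Infinite or undefined event values (zero deviation, perfect
recovery) are excluded from the averages with a logged count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import DRY, NORMAL, WET, EventTable, SeasonClassification

logger = logging.getLogger(__name__)

__all__ = [
    "FACETS",
    "PlotTimeSeries",
    "CoverSeries",
    "mean_normal",
    "temporal_invariability",
    "resistance_value",
    "recovery_value",
    "bray_curtis",
    "multisite_bray",
    "composition_invariability",
    "reference_community",
    "composition_resistance",
    "composition_recovery",
    "hill_diversity",
    "plot_facets",
    "compute_facet_table",
    "deviation_summary",
]

FACETS = ("invariability", "resistance_dry", "resistance_wet", "recovery_dry", "recovery_wet")

#: aspects whose facet values are stored on the natural-log scale
LOG_ASPECTS_DEFAULT = ("biomass", "richness")


@dataclass(frozen=True)
class PlotTimeSeries:
    """One scalar community property (biomass, richness, ...) per year for a plot."""

    site_id: str
    block_id: str
    treatment: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if years.ndim != 1 or years.shape != values.shape:
            raise ValueError("years and values must be 1-D and the same length")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("community property values must be non-negative")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def value_at(self, year: int) -> float | None:
        idx = np.flatnonzero(self.years == year)
        return float(self.values[idx[0]]) if idx.size else None


@dataclass(frozen=True)
class CoverSeries:
    """Per-year species cover vectors for a plot, on a fixed species axis.

    ``matrix`` is years x species, percent cover (totals may exceed 100 for
    multilayer canopies); absences are explicit zeros.
    """

    site_id: str
    block_id: str
    treatment: str
    years: np.ndarray
    species: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.shape != (years.size, len(self.species)):
            raise ValueError("matrix must be years x species")
        if np.any(matrix < 0):
            raise ValueError("cover must be non-negative")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "matrix", matrix)

    def row(self, year: int) -> np.ndarray | None:
        idx = np.flatnonzero(self.years == year)
        return self.matrix[idx[0]] if idx.size else None


# ---------------------------------------------------------------------------
# scalar-aspect primitives


def mean_normal(series: PlotTimeSeries, classification: SeasonClassification) -> float:
    """Mean of the property over normal growing seasons (the 'normal level')."""
    normal = classification.normal_years()
    mask = np.isin(series.years, normal)
    if not mask.any():
        raise ValueError("no normal growing seasons observed; normal level undefined")
    return float(series.values[mask].mean())


def temporal_invariability(series: PlotTimeSeries, ddof: int = 1) -> float:
    """mu / sigma with sigma the sample sd of residuals from a linear trend.

    Detrending removes variation due to directional change over time; the
    residual sd uses the sample (n-1) convention by default.  Returns
    ``inf`` for a perfectly linear series (flagged by the caller).
    """
    if series.years.size < 4:
        raise ValueError("invariability requires at least 4 years")
    slope, intercept = np.polyfit(series.years, series.values, 1)
    resid = series.values - (slope * series.years + intercept)
    sigma = resid.std(ddof=ddof)
    mu = series.values.mean()
    # a perfectly linear series leaves only rounding error in the residuals
    if sigma <= 1e-10 * max(np.abs(series.values).max(), 1e-300):
        return math.inf
    return float(mu / sigma)


def resistance_value(y_normal: float, y_extreme: float) -> float:
    """Yn_bar / |Ye - Yn_bar|; inf when the extreme season sits exactly at the normal level."""
    if y_normal <= 0:
        raise ValueError("normal-season mean must be positive")
    dev = abs(y_extreme - y_normal)
    if dev == 0:
        return math.inf
    return y_normal / dev


def recovery_value(y_normal: float, y_extreme: float, y_after: float) -> float:
    """|Ye - Yn_bar| / |Ye+1 - Yn_bar|; inf for complete recovery, nan if both deviations vanish."""
    dev_e = abs(y_extreme - y_normal)
    dev_a = abs(y_after - y_normal)
    if dev_e == 0 and dev_a == 0:
        return math.nan
    if dev_a == 0:
        return math.inf
    return dev_e / dev_a


# ---------------------------------------------------------------------------
# composition primitives


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Abundance-based Bray-Curtis dissimilarity, 1 - 2*sum(min)/(sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("cover vectors must share the species axis")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("cover must be non-negative")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two empty communities")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def multisite_bray(matrix: np.ndarray) -> float:
    """Total abundance-based multiple-site Bray-Curtis dissimilarity.

    For T communities (rows) with pairwise shared abundance
    ``A_ij = sum_k min(x_ik, x_jk)`` and abundance differences
    ``b_ij = sum_k x_ik - A_ij``::

        ( sum_{i<j} min(b_ij, b_ji) + sum_{i<j} max(b_ij, b_ji) )
        -----------------------------------------------------------
        ( 2*sum A_ij + sum min(b_ij, b_ji) + sum max(b_ij, b_ji) )

    Reduces to pairwise Bray-Curtis at T=2.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a years x species matrix with at least 2 rows")
    if np.any(matrix < 0):
        raise ValueError("cover must be non-negative")
    totals = matrix.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("multiple-site Bray-Curtis undefined with an empty community")
    # pairwise shared abundance via broadcasting: A[i, j] = sum_k min
    shared = np.minimum(matrix[:, None, :], matrix[None, :, :]).sum(axis=2)
    iu = np.triu_indices(matrix.shape[0], k=1)
    a_sum = shared[iu].sum()
    b = totals[:, None] - shared  # b[i, j] = sum_i - A_ij
    b_ij, b_ji = b[iu], b.T[iu]
    min_sum = np.minimum(b_ij, b_ji).sum()
    max_sum = np.maximum(b_ij, b_ji).sum()
    return float((min_sum + max_sum) / (2.0 * a_sum + min_sum + max_sum))


def composition_invariability(cov: CoverSeries) -> float:
    """1 minus the multiple-site dissimilarity over all experimental years."""
    if cov.years.size < 4:
        raise ValueError("composition invariability requires at least 4 years")
    return 1.0 - multisite_bray(cov.matrix)


def reference_community(cov: CoverSeries, classification: SeasonClassification) -> np.ndarray:
    """Per-species mean cover over normal growing seasons (zeros included)."""
    normal = classification.normal_years()
    mask = np.isin(cov.years, normal)
    if not mask.any():
        raise ValueError("no normal growing seasons observed; reference undefined")
    return cov.matrix[mask].mean(axis=0)


def composition_resistance(cov_extreme: np.ndarray, reference: np.ndarray) -> float:
    """Similarity (1 - Bray-Curtis) of the extreme-season community to the reference."""
    return 1.0 - bray_curtis(cov_extreme, reference)


def composition_recovery(
    cov_extreme: np.ndarray, cov_after: np.ndarray, reference: np.ndarray
) -> float:
    """Ratio of after-extreme to during-extreme similarity to the reference."""
    sim_e = 1.0 - bray_curtis(cov_extreme, reference)
    sim_a = 1.0 - bray_curtis(cov_after, reference)
    if sim_e == 0:
        return math.inf
    return sim_a / sim_e


def hill_diversity(cover: np.ndarray, q: float) -> float:
    """Effective species number of order q from a cover vector.

    q=0 is richness, q=1 the exponential of Shannon entropy, q=2 the
    inverse Simpson concentration; larger q weights abundant species more.
    """
    if q < 0:
        raise ValueError("Hill order q must be non-negative")
    cover = np.asarray(cover, dtype=float)
    p = cover[cover > 0]
    if p.size == 0:
        raise ValueError("Hill diversity undefined for an empty community")
    p = p / p.sum()
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


# ---------------------------------------------------------------------------
# per-plot facet assembly


def _mean_events(values: list[float]) -> tuple[float | None, int, int]:
    """Mean of finite event values; returns (mean, n_used, n_dropped)."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    return (float(finite.mean()) if finite.size else None, int(finite.size), int(arr.size - finite.size))


def plot_facets(
    series: PlotTimeSeries,
    classification: SeasonClassification,
    events: EventTable,
) -> dict[str, tuple[float, int]]:
    """All five facets for one scalar-aspect plot series.

    Returns a mapping facet -> (value on the natural scale, n_events); the
    log transform for biomass/richness is applied by the aggregator.
    Facets whose events are all missing or non-finite are omitted.
    """
    out: dict[str, tuple[float, int]] = {}
    if series.years.size >= 4:
        inv = temporal_invariability(series)
        if math.isfinite(inv):
            out["invariability"] = (inv, series.years.size)
        else:
            logger.warning(
                "perfectly linear series for %s/%s/%s: invariability infinite, dropped",
                series.site_id, series.block_id, series.treatment,
            )
    y_normal = mean_normal(series, classification)

    per_kind: dict[str, list[float]] = {f"resistance_{k}": [] for k in (DRY, WET)}
    per_kind.update({f"recovery_{k}": [] for k in (DRY, WET)})
    for year, kind in events.resistance_years:
        y_e = series.value_at(year)
        if y_e is None:
            continue
        per_kind[f"resistance_{kind}"].append(resistance_value(y_normal, y_e))
    for year_e, year_after, kind in events.recovery_pairs:
        y_e = series.value_at(year_e)
        y_a = series.value_at(year_after)
        if y_e is None or y_a is None:
            continue
        per_kind[f"recovery_{kind}"].append(recovery_value(y_normal, y_e, y_a))

    for facet, vals in per_kind.items():
        if not vals:
            continue
        mean, n_used, n_dropped = _mean_events(vals)
        if n_dropped:
            logger.info(
                "%s/%s/%s %s: %d non-finite event value(s) excluded",
                series.site_id, series.block_id, series.treatment, facet, n_dropped,
            )
        if mean is not None:
            out[facet] = (mean, n_used)
    return out


def composition_plot_facets(
    cov: CoverSeries,
    classification: SeasonClassification,
    events: EventTable,
) -> dict[str, tuple[float, int]]:
    """All five facets for one plot's cover series (composition aspect)."""
    out: dict[str, tuple[float, int]] = {}
    if cov.years.size >= 4:
        out["invariability"] = (composition_invariability(cov), cov.years.size)
    ref = reference_community(cov, classification)

    per_kind: dict[str, list[float]] = {f"resistance_{k}": [] for k in (DRY, WET)}
    per_kind.update({f"recovery_{k}": [] for k in (DRY, WET)})
    for year, kind in events.resistance_years:
        row = cov.row(year)
        if row is None:
            continue
        per_kind[f"resistance_{kind}"].append(composition_resistance(row, ref))
    for year_e, year_after, kind in events.recovery_pairs:
        row_e = cov.row(year_e)
        row_a = cov.row(year_after)
        if row_e is None or row_a is None:
            continue
        per_kind[f"recovery_{kind}"].append(composition_recovery(row_e, row_a, ref))

    for facet, vals in per_kind.items():
        if not vals:
            continue
        mean, n_used, n_dropped = _mean_events(vals)
        if n_dropped:
            logger.info(
                "%s/%s/%s composition %s: %d non-finite event value(s) excluded",
                cov.site_id, cov.block_id, cov.treatment, facet, n_dropped,
            )
        if mean is not None:
            out[facet] = (mean, n_used)
    return out


def compute_facet_table(
    scalar_series: dict[str, list[PlotTimeSeries]],
    cover_series: list[CoverSeries],
    classifications: dict[str, SeasonClassification],
    events: dict[str, EventTable],
    log_aspects: tuple[str, ...] = LOG_ASPECTS_DEFAULT,
) -> pd.DataFrame:
    """Tidy facet table over all plots and aspects.

    Parameters
    ----------
    scalar_series
        Mapping aspect name -> list of per-plot time series (e.g.
        ``{"biomass": [...], "richness": [...], "hill_q1": [...]}``).
    cover_series
        Per-plot cover matrices for the composition aspect.
    classifications, events
        Per-site season classification (restricted to experimental years)
        and selected events.
    log_aspects
        Aspects stored on the natural-log scale.  Hill-diversity aspects
        reuse the richness treatment and are logged when listed.

    Returns
    -------
    DataFrame with columns site, block, treatment, aspect, facet, value,
    n_events.
    """
    rows = []

    def emit(site, block, trt, aspect, facets: dict[str, tuple[float, int]]):
        for facet, (value, n_events) in facets.items():
            stored = value
            if aspect in log_aspects:
                if value <= 0:
                    logger.info(
                        "non-positive %s %s for %s/%s/%s cannot be log-transformed; dropped",
                        aspect, facet, site, block, trt,
                    )
                    continue
                stored = math.log(value)
            rows.append(
                dict(site=site, block=block, treatment=trt, aspect=aspect,
                     facet=facet, value=stored, n_events=n_events)
            )

    for aspect, series_list in scalar_series.items():
        for ts in series_list:
            cls = classifications[ts.site_id]
            emit(ts.site_id, ts.block_id, ts.treatment, aspect,
                 plot_facets(ts, cls, events[ts.site_id]))

    for cov in cover_series:
        cls = classifications[cov.site_id]
        emit(cov.site_id, cov.block_id, cov.treatment, "composition",
             composition_plot_facets(cov, cls, events[cov.site_id]))

    return pd.DataFrame(
        rows, columns=["site", "block", "treatment", "aspect", "facet", "value", "n_events"]
    )


def deviation_summary(
    scalar_series: dict[str, list[PlotTimeSeries]],
    cover_series: list[CoverSeries],
    classifications: dict[str, SeasonClassification],
    events: dict[str, EventTable],
) -> pd.DataFrame:
    """Average change and deviation from normal levels during/after extremes.

    For scalar aspects, rows report mean(Y - Yn_bar), mean|Y - Yn_bar| and
    mean((Y - Yn_bar)/Yn_bar) per (treatment, kind, timing); for
    composition, the Bray-Curtis dissimilarity to the reference community
    replaces Y - Yn_bar.
    """
    records = []

    def collect(site_id, trt, aspect, kind, timing, change, y_normal):
        records.append(
            dict(site=site_id, treatment=trt, aspect=aspect, kind=kind, timing=timing,
                 change=change, absolute=abs(change),
                 proportional=change / y_normal if y_normal else np.nan)
        )

    for aspect, series_list in scalar_series.items():
        for ts in series_list:
            cls = classifications[ts.site_id]
            ev = events[ts.site_id]
            y_normal = mean_normal(ts, cls)
            for year, kind in ev.resistance_years:
                y_e = ts.value_at(year)
                if y_e is not None:
                    collect(ts.site_id, ts.treatment, aspect, kind, "during", y_e - y_normal, y_normal)
            for year_e, year_after, kind in ev.recovery_pairs:
                y_a = ts.value_at(year_after)
                if y_a is not None:
                    collect(ts.site_id, ts.treatment, aspect, kind, "after", y_a - y_normal, y_normal)

    for cov in cover_series:
        cls = classifications[cov.site_id]
        ev = events[cov.site_id]
        ref = reference_community(cov, cls)
        for year, kind in ev.resistance_years:
            row = cov.row(year)
            if row is not None:
                d = bray_curtis(row, ref)
                collect(cov.site_id, cov.treatment, "composition", kind, "during", d, 1.0)
        for year_e, year_after, kind in ev.recovery_pairs:
            row = cov.row(year_after)
            if row is not None:
                d = bray_curtis(row, ref)
                collect(cov.site_id, cov.treatment, "composition", kind, "after", d, 1.0)

    df = pd.DataFrame(records)
    if df.empty:
        return df
    return (
        df.groupby(["treatment", "aspect", "kind", "timing"], as_index=False)
        .agg(mean_change=("change", "mean"), mean_absolute=("absolute", "mean"),
             mean_proportional=("proportional", "mean"), n_events=("change", "size"))
    )
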