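"""Growing-season climate standardization and extreme-event selection.

The input to this module is one water-balance value (precipitation minus
potential evapotranspiration, mm) per site per growing season, typically
spanning a long historical baseline (e.g. 1901-2021).  Standardizing that
series over the baseline gives the SPEI (standardized precipitation-
evapotranspiration index) in SD units; seasons are then classified as dry,
normal or wet with a symmetric cutoff, and resistance/recovery events are
selected with rules that guard against consecutive extremes confounding
each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SPEISeries",
    "SeasonClassification",
    "EventTable",
    "standardize",
    "detrend_spei",
    "classify",
    "select_events",
]

DRY = "dry"
NORMAL = "normal"
WET = "wet"

#: cutoffs (in SD units) corresponding to quartile / decile extreme seasons
QUARTILE_CUTOFF = 0.67
DECILE_CUTOFF = 1.28


@dataclass(frozen=True)
class SPEISeries:
    """Annual standardized growing-season water balance for one site.

    Values are dimensionless z-scores: mean 0 and sd 1 over the baseline
    window used for standardization.
    """

    site_id: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if years.shape != values.shape or years.ndim != 1:
            raise ValueError("years and values must be 1-D and the same length")
        if len(np.unique(years)) != len(years):
            raise ValueError("duplicate years in SPEI series")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def restrict(self, years: Sequence[int]) -> "SPEISeries":
        """Subset to the given years (order taken from this series)."""
        mask = np.isin(self.years, np.asarray(years, dtype=int))
        return SPEISeries(self.site_id, self.years[mask], self.values[mask])


@dataclass(frozen=True)
class SeasonClassification:
    """Per-year dry/normal/wet labels for one site at a given cutoff."""

    site_id: str
    cutoff: float
    years: np.ndarray
    labels: np.ndarray
    spei: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        object.__setattr__(self, "spei", np.asarray(self.spei, dtype=float))

    def label_of(self, year: int) -> str:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not classified for site {self.site_id}")
        return str(self.labels[idx[0]])

    def normal_years(self) -> np.ndarray:
        return self.years[self.labels == NORMAL]

    def restrict(self, years: Sequence[int]) -> "SeasonClassification":
        mask = np.isin(self.years, np.asarray(years, dtype=int))
        return SeasonClassification(
            self.site_id, self.cutoff, self.years[mask], self.labels[mask], self.spei[mask]
        )


@dataclass(frozen=True)
class EventTable:
    """Selected extreme-season events for one site.

    ``resistance_years`` holds (year, kind) pairs for which resistance is
    computed; ``recovery_pairs`` holds (extreme_year, after_year, kind)
    triples with after_year = extreme_year + 1.
    """

    site_id: str
    resistance_years: tuple = field(default_factory=tuple)
    recovery_pairs: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for year_e, year_after, _kind in self.recovery_pairs:
            if year_after != year_e + 1:
                raise ValueError("recovery pair must span consecutive years")


def standardize(
    values: Iterable[float],
    years: Iterable[int],
    site_id: str = "",
    baseline: tuple[int, int] | None = None,
    ddof: int = 1,
) -> SPEISeries:
    """Z-score an annual water-balance series over a baseline window.

    Parameters
    ----------
    values, years
        Annual growing-season water balance (any units) and calendar years.
    baseline
        Inclusive (first, last) year range used for the mean and sd; by
        default the whole series.  The sample-sd convention (``ddof=1``) is
        used, matching common SPEI practice.
    """
    years = np.asarray(list(years), dtype=int)
    values = np.asarray(list(values), dtype=float)
    if years.shape != values.shape:
        raise ValueError("years and values must have the same length")
    if baseline is None:
        base = values
    else:
        lo, hi = baseline
        base = values[(years >= lo) & (years <= hi)]
    if base.size < 2:
        raise ValueError("baseline window must contain at least 2 years")
    mu = base.mean()
    sd = base.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero variance in baseline window; cannot standardize")
    return SPEISeries(site_id, years, (values - mu) / sd)


def detrend_spei(series: SPEISeries, restandardize: bool = True) -> SPEISeries:
    """Remove the long-term linear trend from an SPEI series.

    Returns the residuals of a least-squares fit of SPEI against year.  A
    positive (negative) trend inflates the apparent frequency of wet (dry)
    seasons late in the record, which this removes.  With
    ``restandardize=True`` (default) the residuals are rescaled to unit
    sample sd so that classification cutoffs stay in SD units.
    """
    if series.years.size < 3:
        raise ValueError("detrending requires at least 3 years")
    slope, intercept = np.polyfit(series.years, series.values, 1)
    resid = series.values - (slope * series.years + intercept)
    if restandardize:
        sd = resid.std(ddof=1)
        if sd == 0:
            raise ValueError("zero residual variance after detrending")
        resid = resid / sd
    return SPEISeries(series.site_id, series.years, resid)


def classify(series: SPEISeries, cutoff: float = QUARTILE_CUTOFF) -> SeasonClassification:
    """Label each growing season dry, normal or wet.

    dry iff SPEI <= -cutoff, wet iff SPEI >= +cutoff, normal otherwise.
    Boundary values count as extreme, consistent with percentile definitions
    (dry: at or below the 25th percentile for cutoff 0.67).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    labels = np.full(series.values.shape, NORMAL, dtype=object)
    labels[series.values <= -cutoff] = DRY
    labels[series.values >= cutoff] = WET
    return SeasonClassification(series.site_id, cutoff, series.years, labels, series.values)


def select_events(
    classification: SeasonClassification,
    experimental_years: Sequence[int] | None = None,
) -> EventTable:
    """Select resistance years and recovery pairs among experimental seasons.

    Consecutive extremes are handled with two rules.  (1) For two
    consecutive extremes of *different* kinds (e.g. dry then wet), the
    former season contributes resistance only, and the latter contributes
    neither resistance nor recovery.  (2) In a run of consecutive extremes
    of the *same* kind, recovery is computed only for the last season of
    the run, and only when the following season qualifies as a recovery
    season: normal, or — when classifying at the 1.28 SD cutoff — the same
    kind but less extreme.  Resistance is computed for every extreme year
    of a same-kind run (rule 1 permitting).  An extreme in the final
    experimental year yields no recovery pair.  Rules are applied to
    consecutive pairs left to right.
    """
    cls = classification
    if experimental_years is not None:
        cls = cls.restrict(experimental_years)
    order = np.argsort(cls.years)
    years = cls.years[order]
    labels = cls.labels[order]
    spei = cls.spei[order]
    n = years.size
    if n == 0:
        raise ValueError("no classified experimental years")
    if np.any(np.diff(years) != 1) and n > 1:
        # gaps are tolerated: rules apply only to truly consecutive seasons
        pass

    is_extreme = labels != NORMAL
    no_resistance = np.zeros(n, dtype=bool)
    no_recovery = np.zeros(n, dtype=bool)

    for i in range(n - 1):
        if years[i + 1] != years[i] + 1:
            continue
        if is_extreme[i] and is_extreme[i + 1] and labels[i] != labels[i + 1]:
            # rule 1: opposite-kind pair
            no_recovery[i] = True
            no_resistance[i + 1] = True
            no_recovery[i + 1] = True
        # rule 2 (same-kind runs) needs no marking here: it is enforced by
        # the recovery-season qualification below — a same-kind follower is
        # never normal, so only the last season of a run can recover (or,
        # at the 1.28 cutoff, an earlier one into a less extreme follower).

    allow_less_extreme = cls.cutoff >= DECILE_CUTOFF

    resistance = []
    recovery = []
    for i in range(n):
        if not is_extreme[i]:
            continue
        kind = str(labels[i])
        if not no_resistance[i]:
            resistance.append((int(years[i]), kind))
        if no_recovery[i] or i == n - 1 or years[i + 1] != years[i] + 1:
            continue
        nxt_label = labels[i + 1]
        qualifies = nxt_label == NORMAL or (
            allow_less_extreme
            and nxt_label == labels[i]
            and abs(spei[i + 1]) < abs(spei[i])
        )
        if qualifies:
            recovery.append((int(years[i]), int(years[i]) + 1, kind))

    return EventTable(cls.site_id, tuple(resistance), tuple(recovery))
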