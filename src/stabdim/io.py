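"""Readers, validation and data preparation for the plot-level pipeline.

Input is three long-format CSV files:

cover
    site, block, plot, treatment, year, species, cover, survey — percent
    cover per species per survey (sites surveyed twice a year carry
    survey 1 and 2; the maximum per species is used downstream).
biomass
    site, block, plot, treatment, year, biomass — aboveground biomass in
    g m^-2.
climate
    site, year, value, kind — one growing-season value per year, with
    ``kind`` either ``water_balance`` (raw, mm; standardized here) or
    ``spei`` (precomputed z-scores).

Other column dialects (e.g. the public NutNet export's site_code / trt /
Taxon / max_cover / mass) are handled with a remapping table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import NORMAL, SeasonClassification
from .stability import CoverSeries, PlotTimeSeries, hill_diversity

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityPanel",
    "NUTNET_COLMAP",
    "read_inputs",
    "prepare_cover",
    "filter_sites",
]

COVER_COLUMNS = ["site", "block", "plot", "treatment", "year", "species", "cover", "survey"]
BIOMASS_COLUMNS = ["site", "block", "plot", "treatment", "year", "biomass"]
CLIMATE_COLUMNS = ["site", "year", "value", "kind"]
TREATMENTS = {"Control", "NPK"}

#: remapping from the public NutNet export dialect to the canonical columns
NUTNET_COLMAP = {
    "site_code": "site",
    "trt": "treatment",
    "year_trt": "year",
    "Taxon": "species",
    "max_cover": "cover",
    "mass": "biomass",
}


@dataclass
class CommunityPanel:
    """Validated long-format community data (cover + biomass)."""

    cover: pd.DataFrame
    biomass: pd.DataFrame

    def sites(self) -> list[str]:
        return sorted(set(self.cover["site"]).union(self.biomass["site"]))

    def experimental_years(self, site: str) -> np.ndarray:
        years = set(self.cover.loc[self.cover["site"] == site, "year"])
        years |= set(self.biomass.loc[self.biomass["site"] == site, "year"])
        return np.array(sorted(years), dtype=int)

    def restrict_sites(self, keep: list[str]) -> "CommunityPanel":
        return CommunityPanel(
            self.cover[self.cover["site"].isin(keep)].reset_index(drop=True),
            self.biomass[self.biomass["site"].isin(keep)].reset_index(drop=True),
        )

    # ---- per-plot series -------------------------------------------------

    def biomass_series(self) -> list[PlotTimeSeries]:
        out = []
        for (site, block, trt), grp in self.biomass.groupby(["site", "block", "treatment"]):
            grp = grp.sort_values("year")
            out.append(PlotTimeSeries(site, block, trt,
                                      grp["year"].to_numpy(), grp["biomass"].to_numpy()))
        return out

    def cover_series(self) -> list[CoverSeries]:
        return prepare_cover(self.cover)

    def richness_series(self, covers: list[CoverSeries] | None = None) -> list[PlotTimeSeries]:
        covers = self.cover_series() if covers is None else covers
        return [
            PlotTimeSeries(c.site_id, c.block_id, c.treatment, c.years,
                           (c.matrix > 0).sum(axis=1).astype(float))
            for c in covers
        ]

    def hill_series(self, q: float, covers: list[CoverSeries] | None = None) -> list[PlotTimeSeries]:
        covers = self.cover_series() if covers is None else covers
        return [
            PlotTimeSeries(c.site_id, c.block_id, c.treatment, c.years,
                           np.array([hill_diversity(row, q) for row in c.matrix]))
            for c in covers
        ]


def _remap(df: pd.DataFrame, colmap: dict | None) -> pd.DataFrame:
    return df.rename(columns=colmap) if colmap else df


def _require_columns(df: pd.DataFrame, required: list[str], optional: list[str], name: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing column(s): {missing}")
    for c in optional:
        if c not in df.columns:
            df[c] = 1
    return df


def _rows_where(mask: pd.Series) -> str:
    rows = (mask[mask].index + 2).tolist()  # +2: header line plus 1-based
    shown = ", ".join(map(str, rows[:10]))
    return shown + (" ..." if len(rows) > 10 else "")


def read_inputs(
    cover_path: str | Path,
    biomass_path: str | Path,
    climate_path: str | Path,
    colmap: dict | None = None,
) -> tuple[CommunityPanel, pd.DataFrame]:
    """Read and validate the three input CSVs.

    Schema violations (missing columns, negative cover or biomass,
    duplicate cover records) are hard errors reported with file row
    numbers.  Returns the community panel and the raw climate table.
    """
    cover = _remap(pd.read_csv(cover_path), colmap)
    biomass = _remap(pd.read_csv(biomass_path), colmap)
    clim = _remap(pd.read_csv(climate_path), colmap)

    cover = _require_columns(cover, COVER_COLUMNS[:-1], ["survey"], "cover")
    _require_columns(biomass, BIOMASS_COLUMNS, [], "biomass")
    if "kind" not in clim.columns:
        clim["kind"] = "water_balance"
    _require_columns(clim, CLIMATE_COLUMNS, [], "climate")

    neg = cover["cover"] < 0
    if neg.any():
        raise ValueError(f"negative cover in cover.csv at row(s) {_rows_where(neg)}")
    dup = cover.duplicated(subset=["site", "block", "plot", "year", "species", "survey"], keep=False)
    if dup.any():
        raise ValueError(f"duplicate cover record(s) in cover.csv at row(s) {_rows_where(dup)}")
    neg_b = biomass["biomass"] < 0
    if neg_b.any():
        raise ValueError(f"negative biomass in biomass.csv at row(s) {_rows_where(neg_b)}")
    bad_trt = ~cover["treatment"].isin(TREATMENTS)
    if bad_trt.any():
        raise ValueError(
            f"unknown treatment in cover.csv at row(s) {_rows_where(bad_trt)} "
            f"(expected one of {sorted(TREATMENTS)})"
        )
    bad_kind = ~clim["kind"].isin({"water_balance", "spei"})
    if bad_kind.any():
        raise ValueError(f"unknown climate kind at row(s) {_rows_where(bad_kind)}")

    cover = cover[COVER_COLUMNS]
    biomass = biomass[BIOMASS_COLUMNS]
    clim = clim[CLIMATE_COLUMNS]
    logger.info("read %d cover rows, %d biomass rows, %d climate rows",
                len(cover), len(biomass), len(clim))
    return CommunityPanel(cover, biomass), clim


def prepare_cover(cover: pd.DataFrame) -> list[CoverSeries]:
    """Collapse surveys and build one zero-filled cover matrix per plot.

    Within (plot, year) the maximum cover per species over surveys is
    used; the species axis of each plot is the union of species ever
    recorded in that plot, with explicit zeros for absences.
    """
    out = []
    collapsed = (
        cover.groupby(["site", "block", "treatment", "year", "species"], as_index=False)
        ["cover"].max()
    )
    for (site, block, trt), grp in collapsed.groupby(["site", "block", "treatment"]):
        wide = grp.pivot_table(index="year", columns="species", values="cover",
                               aggfunc="first", fill_value=0.0).sort_index()
        out.append(CoverSeries(site, block, trt, wide.index.to_numpy(),
                               tuple(wide.columns), wide.to_numpy(dtype=float)))
    return out


def filter_sites(
    panel: CommunityPanel,
    classifications: dict[str, SeasonClassification],
    min_blocks: int = 3,
    min_years: int = 4,
    require_extreme: bool = True,
) -> CommunityPanel:
    """Apply the site-inclusion criteria.

    Keeps sites with >= ``min_blocks`` blocks, >= ``min_years``
    experimental years, at least one dry or wet growing season during the
    experiment (when ``require_extreme``), and at least one normal season
    (the normal level must be defined).  Logs the retained/dropped tallies
    and the dry/normal/wet season counts of the retained sites.
    """
    keep, tallies = [], {"dry": 0, "normal": 0, "wet": 0}
    for site in panel.sites():
        years = panel.experimental_years(site)
        n_blocks = panel.cover.loc[panel.cover["site"] == site, "block"].nunique()
        if n_blocks < min_blocks:
            logger.info("dropping %s: %d block(s) < %d", site, n_blocks, min_blocks)
            continue
        if years.size < min_years:
            logger.info("dropping %s: %d experimental year(s) < %d", site, years.size, min_years)
            continue
        if site not in classifications:
            logger.info("dropping %s: no climate classification", site)
            continue
        cls = classifications[site].restrict(years)
        if cls.years.size < years.size:
            logger.info("dropping %s: climate missing for some experimental years", site)
            continue
        labels = cls.labels
        if require_extreme and not np.any(labels != NORMAL):
            logger.info("dropping %s: no dry or wet growing season recorded", site)
            continue
        if not np.any(labels == NORMAL):
            logger.info("dropping %s: no normal growing season (normal level undefined)", site)
            continue
        keep.append(site)
        for lab in labels:
            tallies[str(lab)] += 1
    if not keep:
        raise ValueError("no sites satisfy the inclusion criteria")
    logger.info("retained %d/%d sites; seasons among retained sites: %d dry / %d normal / %d wet",
                len(keep), len(panel.sites()), tallies["dry"], tallies["normal"], tallies["wet"])
    return panel.restrict_sites(keep)
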